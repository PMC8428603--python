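# suspected re-entrant loop segments
16 42 purple reentrant_loop_1 3
105 131 purple reentrant_loop_2 4
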