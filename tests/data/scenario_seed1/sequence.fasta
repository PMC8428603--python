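>synthetic_membrane_protein seed=1
LMSYADTWFHVKGTGKPMCAVSTMTHLSDHDLYDIKWFMGASCGLLDYRYCRGMWGREHY
KMGDKPLSIPSWKARMVLICLPSVFNTGHTNMQMYSCDMTCQSSVENTIELCFVQVTVHL
PGWATPGRKTYGLFQPTTYY
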