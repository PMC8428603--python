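"""Synthetic input generators: helix models, RR text, and a full demo scenario.

Everything here is synthetic and deterministic given a seed.  The scenario
generator emulates the kind of data a membrane-protein analysis brings
together — a topology prediction with two re-entrant segments, matching
secondary-structure and conservation tracks, a predicted contact map, and a
structural model realizing most of the predicted contacts — without using any
real predictor output or database entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .compare import satisfaction_score, superpose
from .errors import ValidationError
from .layout import FigureSpec, assign_track
from .model import DEFAULT_DISTANCE_BINS, ContactMap, MatchClassification, canonicalize
from .parsers import (
    instructions_to_track,
    parse_consurf,
    parse_custom_track,
    parse_psipred_ss2,
    parse_rr_contacts,
    parse_topcons,
    write_rr,
)
from .structure import extract_contacts, load_model

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_AA1 = "ACDEFGHIKLMNPQRSTVWY"


def _pdb_from_points(
    points: list[tuple[float, float, float]],
    sequence: str,
    cb_points: list[tuple[float, float, float]] | None = None,
    chain_name: str = "A",
) -> str:
    """Write one chain of residues, each with a CA atom (and CB unless glycine)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_name)
    for idx, (ca, aa) in enumerate(zip(points, sequence), start=1):
        res = gemmi.Residue()
        res.name = _AA3[aa]
        res.seqid = gemmi.SeqId(idx, " ")
        res.het_flag = "A"
        for name, pos in (("CA", ca), ("CB", None if aa == "G" else (
            cb_points[idx - 1] if cb_points is not None else ca
        ))):
            if pos is None:
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.pos = gemmi.Position(*pos)
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def make_helix_pdb(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    sequence: str | None = None,
) -> str:
    """PDB text for an ideal helix with CA and CB atoms.

    Default parameters are those of an α-helix (1.5 Å rise and 100° twist per
    residue, 2.3 Å Cα radius), so residues (i, i+3) and (i, i+4) fall within
    the 8 Å contact cutoff while (i, i+5) and beyond do not — the classic
    near-diagonal helix band.  CB atoms sit 1.5 Å further from the axis.
    """
    if n_residues < 4:
        raise ValidationError(f"a helix needs at least 4 residues, got {n_residues}")
    if sequence is None:
        sequence = ("ALEKVH" * (n_residues // 6 + 1))[:n_residues]
    if len(sequence) != n_residues:
        raise ValidationError("sequence length must equal n_residues")
    ca, cb = [], []
    for k in range(n_residues):
        angle = math.radians(twist * k)
        z = rise * k
        ca.append((radius * math.cos(angle), radius * math.sin(angle), z))
        cb.append(((radius + 1.5) * math.cos(angle), (radius + 1.5) * math.sin(angle), z))
    return _pdb_from_points(ca, sequence, cb)


def make_rr(
    cmap: ContactMap,
    dialect: str = "5col",
    bins: tuple[tuple[float, float], ...] = DEFAULT_DISTANCE_BINS,
    distances: dict[tuple[int, int], float] | None = None,
) -> str:
    """Serialize a contact map as RR text in a chosen dialect.

    ``3col`` / ``5col`` emit plain contact records that round-trip exactly
    through the contact parser.  ``rmode2`` emits binned-distance records with
    a one-hot probability vector per pair, placed in the bin containing the
    pair's assigned distance (``distances``; default 5.0 Å for every pair).
    """
    if len(cmap) == 0:
        raise ValidationError("cannot serialize an empty contact map")
    if dialect in ("3col", "5col"):
        return write_rr(cmap, dialect=dialect)
    if dialect != "rmode2":
        raise ValidationError(f"unknown RR dialect {dialect!r}")
    lines = ["PFRMAT RR", "RMODE 2"]
    if cmap.sequence:
        lines.append(cmap.sequence)
    lines.append("MODEL 1")
    for c in cmap.contacts:
        d = 5.0 if distances is None else distances[(c.i, c.j)]
        vec = ["0.000000"] * len(bins)
        for b, (lo, hi) in enumerate(bins):
            if lo < d <= hi:
                vec[b] = "1.000000"
                break
        else:
            raise ValidationError(f"distance {d} outside configured bins")
        lines.append(f"{c.i} {c.j} " + " ".join(vec))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# demo scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ScenarioBundle:
    """Deterministic synthetic input bundle for one membrane-protein scenario."""

    seq_length: int
    fasta: str
    topology: str
    ss2: str
    consurf: str
    custom_track: str
    predicted_rr: str
    model_pdb: str

    def files(self) -> dict[str, str]:
        return {
            "sequence.fasta": self.fasta,
            "topology.txt": self.topology,
            "secondary.ss2": self.ss2,
            "conservation.txt": self.consurf,
            "custom_track.txt": self.custom_track,
            "predicted.rr": self.predicted_rr,
            "model.pdb": self.model_pdb,
        }

    def write(self, directory) -> dict[str, str]:
        import os

        os.makedirs(directory, exist_ok=True)
        paths = {}
        for name, text in self.files().items():
            path = os.path.join(directory, name)
            with open(path, "w") as fh:
                fh.write(text)
            paths[name] = path
        return paths


# residue ranges of the scenario's structural elements (1-based, inclusive)
SCENARIO_LENGTH = 140
SCENARIO_HELICES = ((16, 25), (28, 42), (105, 116), (119, 131))
SCENARIO_REENTRANT = ((16, 42), (105, 131))


def _scenario_coordinates() -> list[tuple[float, float, float]]:
    """Backbone layout: two helical hairpins packed side by side.

    Hairpin 1 (residues 16-25 and 28-42, antiparallel, 6 Å apart) and hairpin
    2 (residues 105-116 and 119-131) sit in parallel planes 6 Å apart, so the
    two re-entrant segments are in mutual long-range contact.  All other
    residues lie on a well-separated extended line and contribute no
    non-sequential contacts.
    """
    coords: dict[int, tuple[float, float, float]] = {}
    for r in range(1, SCENARIO_LENGTH + 1):
        coords[r] = (4.5 * r, -60.0, 0.0)
    for k, r in enumerate(range(16, 26)):       # helix 1, up
        coords[r] = (0.0, 0.0, 1.5 * k)
    coords[26] = (2.0, 0.0, 15.5)               # hairpin turn
    coords[27] = (4.0, 0.0, 15.5)
    for m, r in enumerate(range(28, 43)):       # helix 2, down
        coords[r] = (6.0, 0.0, 13.5 - 1.5 * m)
    for k, r in enumerate(range(105, 117)):     # helix 3, up
        coords[r] = (0.0, 6.0, 1.5 * k)
    coords[117] = (2.0, 6.0, 18.5)
    coords[118] = (4.0, 6.0, 18.5)
    for m, r in enumerate(range(119, 132)):     # helix 4, down
        coords[r] = (6.0, 6.0, 16.5 - 1.5 * m)
    return [coords[r] for r in range(1, SCENARIO_LENGTH + 1)]


def make_membrane_protein_scenario(seed: int = 1) -> ScenarioBundle:
    """Build the deterministic demo bundle (see module docstring).

    The rendered figure for this bundle shows the motif of a re-entrant loop
    analysis: a membrane band on the central track with a break between two
    helix segments that are in mutual contact, and two purple custom-track
    segments marking the suspected re-entrant regions.
    """
    rng = np.random.default_rng(seed)
    L = SCENARIO_LENGTH
    sequence = "".join(rng.choice(list(_AA1), size=L))

    fasta = f">synthetic_membrane_protein seed={seed}\n"
    for start in range(0, L, 60):
        fasta += sequence[start:start + 60] + "\n"

    in_helix = [False] * (L + 1)
    for a, b in SCENARIO_HELICES:
        for r in range(a, b + 1):
            in_helix[r] = True

    topology = []
    for r in range(1, L + 1):
        if in_helix[r]:
            topology.append("M")
        elif r in (26, 27, 117, 118):
            topology.append("i")  # central break of each re-entrant segment
        else:
            topology.append("o")
    topology_text = "".join(topology) + "\n"

    ss2_lines = ["# PSIPRED VFORMAT (synthetic)", ""]
    for r in range(1, L + 1):
        state = "H" if in_helix[r] else "C"
        p = round(0.75 + 0.2 * rng.random(), 3)
        rest = round((1.0 - p) / 2, 3)
        pc, ph, pe = (rest, p, rest) if state == "H" else (p, rest, rest)
        ss2_lines.append(f"{r:4d} {sequence[r - 1]} {state}  {pc:.3f} {ph:.3f} {pe:.3f}")
    ss2_text = "\n".join(ss2_lines) + "\n"

    conserved = [False] * (L + 1)
    for a, b in SCENARIO_REENTRANT:
        for r in range(a, b + 1):
            conserved[r] = True
    consurf_lines = ["# POS SEQ GRADE"]
    for r in range(1, L + 1):
        grade = int(rng.integers(8, 10)) if conserved[r] else int(rng.integers(1, 7))
        consurf_lines.append(f"{r} {sequence[r - 1]} {grade}")
    consurf_text = "\n".join(consurf_lines) + "\n"

    (a1, b1), (a2, b2) = SCENARIO_REENTRANT
    custom_text = (
        "# suspected re-entrant loop segments\n"
        f"{a1} {b1} purple reentrant_loop_1 3\n"
        f"{a2} {b2} purple reentrant_loop_2 4\n"
    )

    model_pdb = _pdb_from_points(_scenario_coordinates(), sequence)

    model_map = extract_contacts(load_model(model_pdb), distance_cutoff=8.0, min_sep=5)
    raw: list[tuple[int, int, float]] = []
    for c in model_map.contacts:
        if rng.random() < 0.8:  # predictor finds most true contacts
            raw.append((c.i, c.j, round(0.70 + 0.29 * rng.random(), 4)))
    existing = model_map.pairs()
    n_decoys = 0
    while n_decoys < 20:  # plus false-positive predictions, some confident
        i = int(rng.integers(1, L - 23))
        j = int(rng.integers(i + 23, L + 1))
        if (i, j) not in existing and all((i, j) != (ri, rj) for ri, rj, _ in raw):
            raw.append((i, j, round(0.30 + 0.69 * rng.random(), 4)))
            n_decoys += 1
    predicted = canonicalize(raw, seq_length=L, sequence=sequence)
    predicted_rr = write_rr(predicted, dialect="5col")

    return ScenarioBundle(
        seq_length=L,
        fasta=fasta,
        topology=topology_text,
        ss2=ss2_text,
        consurf=consurf_text,
        custom_track=custom_text,
        predicted_rr=predicted_rr,
        model_pdb=model_pdb,
    )


def build_scenario_figure(
    bundle: ScenarioBundle, display_min_sep: int = 10
) -> tuple[FigureSpec, MatchClassification, float]:
    """Assemble the demo figure from a scenario bundle.

    Parses every bundle file, extracts the model map (Cβ 8 Å), superposes it
    with the predicted map at ``display_min_sep`` (kept clear of the 9-residue
    track zone), and lays out: match classification above the diagonal, the
    predicted map below, topology on slot 0, secondary structure mirrored on
    ±1, conservation mirrored on ±2 and the custom re-entrant-loop segments
    mirrored on ±3/±4.  Returns the figure spec, the classification and the
    long-range top-L/2 satisfaction score.
    """
    predicted = parse_rr_contacts(bundle.predicted_rr)
    model_map = extract_contacts(
        load_model(bundle.model_pdb), distance_cutoff=8.0, min_sep=5
    )
    classification = superpose(predicted, model_map, min_sep=display_min_sep)
    score = satisfaction_score(predicted, model_map)

    spec = FigureSpec(
        seq_length=bundle.seq_length,
        upper_map=classification,
        lower_map=predicted,
        min_sep=display_min_sep,
    )
    assign_track(spec, 0, parse_topcons(bundle.topology))
    assign_track(spec, 1, parse_psipred_ss2(bundle.ss2), mirror=True)
    assign_track(spec, 2, parse_consurf(bundle.consurf), mirror=True)
    custom = parse_custom_track(bundle.custom_track)
    for slot in (3, 4):
        instructions = [c for c in custom if c.slot_hint == slot]
        assign_track(
            spec, slot,
            instructions_to_track(instructions, bundle.seq_length, name=f"custom {slot}"),
            mirror=True,
        )
    return spec, classification, score
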