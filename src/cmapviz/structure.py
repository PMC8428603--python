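"""Extract model-derived contact maps from PDB coordinates.

One representative atom is chosen per residue — Cβ, falling back to Cα for
glycine or when Cβ is missing (the CASP convention); a Cα-only scheme is also
available.  Residues are renumbered 1..N in chain order so model maps align
with prediction maps, while author numbers are retained for reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .model import ContactMap, ResidueContact

#: Representative-atom distance (Å) below which two residues are in contact.
DEFAULT_CONTACT_CUTOFF = 8.0


@dataclass(frozen=True, slots=True)
class ResidueCoordinates:
    """Representative-atom position for one residue of one chain."""

    chain: str
    seq_index: int          # 1-based position in chain order
    author_number: int      # residue number as written in the file
    name: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValidationError(
                f"non-finite coordinates for residue {self.author_number}"
            )

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _representative_atom(residue: gemmi.Residue, scheme: str) -> gemmi.Atom | None:
    """Pick the representative atom; highest occupancy wins among altlocs."""
    names = ["CA"] if scheme == "CA" else ["CB", "CA"]
    for name in names:
        candidates = [a for a in residue if a.name == name]
        if candidates:
            return max(candidates, key=lambda a: a.occ)
    return None


def load_model(
    pdb_text: str, chain: str | None = None, scheme: str = "CB"
) -> list[ResidueCoordinates]:
    """Read PDB text and return representative-atom coordinates for one chain.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file with ATOM records.
    chain:
        Chain identifier; the first chain is used when omitted.
    scheme:
        ``"CB"`` (Cβ, Cα fallback — the default contact convention) or
        ``"CA"`` (Cα only).

    Residues lacking a representative atom are skipped with a warning.
    Discontinuous author numbering is preserved in ``author_number`` but the
    returned ``seq_index`` always runs 1..N in chain order.
    """
    if scheme not in ("CB", "CA"):
        raise ValidationError(f"unknown atom scheme {scheme!r}")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValidationError("no ATOM records found in PDB input")
    model = st[0]
    polymer_chain: gemmi.Chain | None = None
    for ch in model:
        if chain is None or ch.name == chain:
            polymer_chain = ch
            break
    if polymer_chain is None:
        raise ValidationError(f"chain {chain!r} not found")
    out: list[ResidueCoordinates] = []
    seq_index = 0
    for residue in polymer_chain:
        if residue.het_flag != "A":  # skip HETATM (waters, ligands)
            continue
        atom = _representative_atom(residue, scheme)
        if atom is None:
            warnings.warn(
                f"residue {residue.name} {residue.seqid.num}: no CB or CA atom, skipped"
            )
            continue
        seq_index += 1
        out.append(
            ResidueCoordinates(
                chain=polymer_chain.name,
                seq_index=seq_index,
                author_number=residue.seqid.num,
                name=residue.name,
                x=atom.pos.x,
                y=atom.pos.y,
                z=atom.pos.z,
            )
        )
    if not out:
        raise ValidationError("no ATOM records found in selected chain")
    return out


def numbering_report(residues: list[ResidueCoordinates]) -> list[tuple[int, int]]:
    """``(seq_index, author_number)`` pairs; useful when author numbering has gaps."""
    return [(r.seq_index, r.author_number) for r in residues]


def extract_contacts(
    residues: list[ResidueCoordinates],
    distance_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_sep: int = 0,
) -> ContactMap:
    """Contacts between residues whose representative atoms lie within the cutoff.

    A pair ``(i, j)`` is a contact iff the representative-atom distance is
    <= ``distance_cutoff`` and the sequence separation ``|i - j|`` is
    >= ``min_sep``.  All contact scores are 1.0.  Neighbour search uses a k-d
    tree; results are identical to the all-pairs distance computation.
    """
    if len(residues) < 2:
        raise ValidationError("need at least 2 residues to extract contacts")
    if distance_cutoff <= 0:
        raise ValidationError(f"distance cutoff must be > 0, got {distance_cutoff}")
    coords = np.array([[r.x, r.y, r.z] for r in residues])
    index = np.array([r.seq_index for r in residues])
    tree = cKDTree(coords)
    contacts = []
    for a, b in tree.query_pairs(distance_cutoff):
        i, j = sorted((int(index[a]), int(index[b])))
        if j - i >= min_sep:
            contacts.append(ResidueContact(i, j, 1.0))
    return ContactMap(int(index.max()), contacts)
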