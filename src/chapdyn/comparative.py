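"""Alignment-guided structural comparison and client-segment descriptors.

Global (Needleman-Wunsch) sequence alignment with the BLOSUM62 matrix and
affine gaps drives C-alpha correspondence for Kabsch superposition and
RMSD — including the protomer-asymmetry analysis of a chaperone dimer
(aligning the two protomer chains onto each other).  Client-segment
physicochemistry: GRAVY (mean Kyte-Doolittle hydropathy), percent
hydrophobic residues, and isoelectric point by bisection on the
Henderson-Hasselbalch net charge with the EMBOSS pKa set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from chapdyn.core_io import MolecularStructure
from chapdyn.geometry import apply_transform, kabsch, rmsd

__all__ = [
    "AlignmentResult",
    "SuperpositionResult",
    "SegmentDescriptors",
    "EMBOSS_PKA",
    "KYTE_DOOLITTLE",
    "global_align",
    "superpose",
    "protomer_asymmetry",
    "net_charge",
    "isoelectric_point",
    "segment_descriptors",
]

# EMBOSS pKa values (side chains and termini)
EMBOSS_PKA = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
    "Nterm": 8.6, "Cterm": 3.6,
}
_ACIDIC = {"D", "E", "C", "Y"}
_BASIC = {"K", "R", "H"}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
HYDROPHOBIC = set("AVLIMFWCP")


@dataclass
class AlignmentResult:
    """Pairwise global alignment with identity/similarity percentages.

    Identity = identical pairs / aligned columns between the first and
    last column where both sequences have a residue (terminal overhangs
    excluded); similarity counts pairs with positive BLOSUM62 score.
    ``identity_short`` uses the shorter-sequence length as denominator.
    Invariant: identity <= similarity <= 100.
    """

    aligned_a: str
    aligned_b: str
    score: float
    correspondence: list  # [(index_in_a, index_in_b), ...] for matched columns
    percent_identity: float
    percent_similarity: float
    identity_short: float
    gap_open: float
    gap_extend: float


def _blosum62_with_neutral_x():
    mat = substitution_matrices.load("BLOSUM62")
    arr = np.array(mat)
    alphabet = mat.alphabet
    if "X" in alphabet:
        xi = alphabet.index("X")
        arr[xi, :] = 0.0
        arr[:, xi] = 0.0
    return substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)


_BLOSUM62 = _blosum62_with_neutral_x()


def global_align(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment (Needleman-Wunsch, BLOSUM62, affine gaps).

    X is scored 0 against everything.  The first optimal traceback is
    taken, which is deterministic.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for s in (seq_a, seq_b):
        bad = set(s) - set(_BLOSUM62.alphabet)
        if bad:
            raise ValueError(f"sequence contains letters outside the alignment alphabet: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    sa, sb = str(aln[0]), str(aln[1])

    # trim terminal overhangs for the identity denominator
    both = [k for k in range(len(sa)) if sa[k] != "-" and sb[k] != "-"]
    if not both:
        core = range(0)
    else:
        core = range(both[0], both[-1] + 1)
    ncols = len(core) or 1
    ident = 0
    similar = 0
    correspondence = []
    ia = ib = 0
    for k in range(len(sa)):
        ca, cb = sa[k], sb[k]
        if ca != "-" and cb != "-":
            correspondence.append((ia, ib))
            if k in core:
                if ca == cb:
                    ident += 1
                # identical pairs are always similar (X-X scores 0 but matches)
                if ca == cb or _BLOSUM62[ca, cb] > 0:
                    similar += 1
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return AlignmentResult(
        aligned_a=sa,
        aligned_b=sb,
        score=float(aln.score),
        correspondence=correspondence,
        percent_identity=100.0 * ident / ncols,
        percent_similarity=100.0 * similar / ncols,
        identity_short=100.0 * ident / min(len(seq_a), len(seq_b)),
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


@dataclass
class SuperpositionResult:
    """Least-squares rigid superposition: rotation (det +1), translation,
    C-alpha RMSD (A) over the matched pairs."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int
    per_pair_deviation: np.ndarray | None = None


def _ca_coords_by_residue(structure: MolecularStructure, chain_id: str | None, atom_name: str):
    """Ordered (res_uid, coord) list of the named atom per residue."""
    out = []
    for a in structure.atoms:
        if a.name == atom_name and not a.het and (chain_id is None or a.chain_id == chain_id):
            out.append((a.res_uid, a.xyz))
    return out


def superpose(
    struct_a: MolecularStructure,
    struct_b: MolecularStructure,
    correspondence: list | None = None,
    atom_name: str = "CA",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> SuperpositionResult:
    """Kabsch superposition of A onto B over matched residues.

    ``correspondence`` pairs residue positions (indices into the per-chain
    residue list); by default residues are paired in order.  RMSD is
    computed over the matched ``atom_name`` atoms after the optimal
    transform.
    """
    ca_a = _ca_coords_by_residue(struct_a, chain_a, atom_name)
    ca_b = _ca_coords_by_residue(struct_b, chain_b, atom_name)
    if correspondence is None:
        n = min(len(ca_a), len(ca_b))
        correspondence = [(i, i) for i in range(n)]
    if len(correspondence) < 3:
        raise ValueError("superposition requires at least 3 matched residue pairs")
    pa = np.array([ca_a[i][1] for i, _ in correspondence])
    pb = np.array([ca_b[j][1] for _, j in correspondence])
    rot, trans = kabsch(pa, pb)
    moved = apply_transform(pa, rot, trans)
    dev = np.linalg.norm(moved - pb, axis=1)
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd=rmsd(moved, pb),
        n_matched=len(correspondence),
        per_pair_deviation=dev,
    )


def protomer_asymmetry(
    structure: MolecularStructure,
    chain_a: str,
    chain_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[SuperpositionResult, AlignmentResult]:
    """Superpose the two protomer chains of a dimer onto each other.

    The chains' sequences are globally aligned to obtain the residue
    correspondence, then C-alphas are Kabsch-fitted.  The per-pair
    deviation profile locates asymmetric regions.  Warns when the chains
    share < 30% identity (probably not protomers of the same protein).
    """
    for c in (chain_a, chain_b):
        if c not in structure.chains:
            raise ValueError(f"chain {c!r} not present in structure")
    seq_a = structure.chain_sequence(chain_a)
    seq_b = structure.chain_sequence(chain_b)
    aln = global_align(seq_a, seq_b, gap_open, gap_extend)
    if aln.percent_identity < 30.0:
        warnings.warn(
            f"chains {chain_a}/{chain_b} share only {aln.percent_identity:.0f}% identity; "
            "they may not be protomers of the same protein",
            stacklevel=2,
        )
    sup = superpose(structure, structure, aln.correspondence, chain_a=chain_a, chain_b=chain_b)
    return sup, aln


def net_charge(sequence: str, ph: float, pka: dict | None = None) -> float:
    """Henderson-Hasselbalch net charge Z(pH), termini included."""
    pka = pka or EMBOSS_PKA
    z = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    z -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in sequence:
        if aa in _BASIC and aa in pka:
            z += 1.0 / (1.0 + 10.0 ** (ph - pka[aa]))
        elif aa in _ACIDIC and aa in pka:
            z -= 1.0 / (1.0 + 10.0 ** (pka[aa] - ph))
    return z


def isoelectric_point(sequence: str, pka: dict | None = None, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Z(pH) is strictly decreasing, so the root is unique; bisection runs
    until |Z| < tol.
    """
    lo, hi = 0.0, 14.0
    mid = 7.0
    # bisect the pH interval below 1e-8 so the root is located to machine
    # pH precision even where Z(pH) is nearly flat; |Z| < tol then holds too
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        z = net_charge(sequence, mid, pka)
        if z > 0:
            lo = mid
        else:
            hi = mid
    assert abs(net_charge(sequence, mid, pka)) < tol
    return mid


@dataclass
class SegmentDescriptors:
    """Physicochemical descriptors of a client segment."""

    sequence: str
    gravy: float
    percent_hydrophobic: float
    isoelectric_point: float


def segment_descriptors(
    sequence: str,
    pka: dict | None = None,
    hydro_scale: dict | None = None,
) -> SegmentDescriptors:
    """GRAVY, percent hydrophobic residues (AVLIMFWCP), and pI."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    scale = hydro_scale or KYTE_DOOLITTLE
    unknown = [aa for aa in sequence if aa not in scale]
    if unknown:
        raise ValueError(f"unknown residue letters: {sorted(set(unknown))}")
    gravy = float(np.mean([scale[aa] for aa in sequence]))
    phobic = 100.0 * sum(aa in HYDROPHOBIC for aa in sequence) / len(sequence)
    pi = isoelectric_point(sequence, pka)
    return SegmentDescriptors(
        sequence=sequence, gravy=gravy, percent_hydrophobic=phobic, isoelectric_point=pi
    )
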