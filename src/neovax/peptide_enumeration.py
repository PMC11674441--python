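"""Mutant peptide enumeration around amino-acid changes.

From a wild-type protein and one or more residue substitutions, build the
mutant protein and enumerate every window of 8-11 residues (HLA class I
candidates) or 15-18 residues (HLA class II candidates) that covers all
changed positions, clipped at the protein ends.  Also classifies the
sequence relationship between a long (class II) and a short (class I)
peptide: the short epitope may be contained in the long peptide or merely
share a terminal overlap with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .synthetic_data import AMINO_ACIDS, InputError, translate_cds

CLASS_I_LENGTHS = (8, 11)
CLASS_II_LENGTHS = (15, 18)

CANDIDATE_COLUMNS = [
    "gene", "aa_change", "cls", "peptide", "wt_peptide", "start", "k", "mutated_offsets",
]


@dataclass(frozen=True)
class ProteinContext:
    """A wild-type protein with 1-based residue substitutions."""

    gene: str
    protein: str
    changes: tuple[tuple[int, str, str], ...]  # (pos, wt, mut)

    def __post_init__(self) -> None:
        if not self.protein or any(c not in AMINO_ACIDS for c in self.protein):
            raise InputError(f"{self.gene}: protein must be uppercase 20-letter amino acids")
        for pos, wt, mut in self.changes:
            if not (1 <= pos <= len(self.protein)):
                raise InputError(f"{self.gene}: change position {pos} outside protein of length {len(self.protein)}")
            if self.protein[pos - 1] != wt:
                raise InputError(
                    f"{self.gene}: wild-type mismatch at position {pos}: "
                    f"protein has {self.protein[pos - 1]}, change says {wt}"
                )
            if mut not in AMINO_ACIDS:
                raise InputError(f"{self.gene}: mutant residue {mut!r} is not a standard amino acid")

    @property
    def aa_change(self) -> str:
        return " ".join(f"{wt}{pos}{mut}" for pos, wt, mut in self.changes)


@dataclass(frozen=True)
class PeptideCandidate:
    peptide: str
    gene: str
    aa_change: str
    cls: str  # "I" or "II"
    start_in_protein: int  # 1-based
    mutated_offsets: tuple[int, ...]  # 0-based within peptide
    wt_peptide: str = ""


@dataclass(frozen=True)
class Relationship:
    kind: str  # contained | overlap | disjoint
    offset: int | None = None  # 0-based start of short within long (contained)
    overlap_len: int | None = None  # residues shared terminally (overlap)


def mutant_protein(ctx: ProteinContext) -> str:
    """Apply every substitution; the length is unchanged."""
    seq = list(ctx.protein)
    for pos, _wt, mut in ctx.changes:
        seq[pos - 1] = mut
    return "".join(seq)


def enumerate_candidates(
    ctx: ProteinContext,
    cls: str = "I",
    kmin: int | None = None,
    kmax: int | None = None,
) -> list[PeptideCandidate]:
    """All k-mers of the mutant protein covering every changed residue.

    Lengths default to 8-11 for class I and 15-18 for class II.  Windows are
    clipped at protein ends, deduplicated by (peptide, start), and sorted by
    (k, start).  Multi-residue changes require a single window covering all
    changed positions; if they are spread wider than ``kmax`` the result is
    empty with a warning.
    """
    if cls not in ("I", "II"):
        raise InputError(f"cls must be 'I' or 'II', got {cls!r}")
    lo, hi = CLASS_I_LENGTHS if cls == "I" else CLASS_II_LENGTHS
    kmin = lo if kmin is None else kmin
    kmax = hi if kmax is None else kmax
    if kmin > kmax or kmin < 1:
        raise InputError(f"invalid length bounds ({kmin}, {kmax})")
    if not ctx.changes:
        return []
    mut = mutant_protein(ctx)
    positions = sorted(pos for pos, _, _ in ctx.changes)
    first, last = positions[0], positions[-1]
    if last - first + 1 > kmax:
        warnings.warn(
            f"{ctx.gene}: changed residues span {last - first + 1} > kmax={kmax}; no candidate windows"
        )
        return []
    out = []
    seen = set()
    n = len(mut)
    for k in range(kmin, kmax + 1):
        # window [s, s+k-1] (1-based) must satisfy s <= first and s+k-1 >= last
        for s in range(max(1, last - k + 1), min(first, n - k + 1) + 1):
            pep = mut[s - 1: s + k - 1]
            if (pep, s) in seen:
                continue
            seen.add((pep, s))
            out.append(PeptideCandidate(
                peptide=pep,
                gene=ctx.gene,
                aa_change=ctx.aa_change,
                cls=cls,
                start_in_protein=s,
                mutated_offsets=tuple(p - s for p in positions),
                wt_peptide=ctx.protein[s - 1: s + k - 1],
            ))
    return out


def relationship(long: str, short: str, min_overlap: int = 1) -> Relationship:
    """Classify how a short epitope sits relative to a long peptide.

    ``contained`` when the short sequence occurs contiguously in the long
    one (leftmost offset reported); otherwise ``overlap`` with the maximal
    terminal overlap of at least ``min_overlap`` residues (a suffix of one
    equal to a prefix of the other); otherwise ``disjoint``.
    """
    if not long or not short:
        raise InputError("both sequences must be non-empty")
    idx = long.find(short)
    if idx >= 0:
        return Relationship(kind="contained", offset=idx)
    best = 0
    max_k = min(len(long), len(short)) - 1
    for k in range(max_k, max(min_overlap, 1) - 1, -1):
        if long[-k:] == short[:k] or short[-k:] == long[:k]:
            best = k
            break
    if best:
        return Relationship(kind="overlap", overlap_len=best)
    return Relationship(kind="disjoint")


# ---------------------------------------------------------------------------
# bridging calls -> protein contexts, and tabular output
# ---------------------------------------------------------------------------

_AA_CHANGE_RE = r"^([A-Z])(\d+)([A-Z*])$"


def parse_aa_change(aa_change: str) -> list[tuple[int, str, str]]:
    """Parse ``"D542V"`` or ``"I1375R L1376R"`` into (pos, wt, mut) tuples."""
    import re

    changes = []
    for token in aa_change.split():
        m = re.match(_AA_CHANGE_RE, token)
        if not m:
            raise InputError(f"cannot parse amino-acid change token {token!r}")
        changes.append((int(m.group(2)), m.group(1), m.group(3)))
    return changes


def contexts_from_calls(calls: pd.DataFrame, cds: dict[str, str]) -> list[ProteinContext]:
    """Build a ProteinContext per missense call from annotated calls + CDS models."""
    contexts = []
    for r in calls.itertuples(index=False):
        if getattr(r, "effect", "") != "missense":
            continue
        protein = translate_cds(cds[r.transcript_id])
        contexts.append(ProteinContext(
            gene=r.gene,
            protein=protein,
            changes=tuple(parse_aa_change(r.aa_change)),
        ))
    return contexts


def candidates_to_frame(candidates: list[PeptideCandidate]) -> pd.DataFrame:
    rows = [
        (c.gene, c.aa_change, c.cls, c.peptide, c.wt_peptide, c.start_in_protein,
         len(c.peptide), ",".join(map(str, c.mutated_offsets)))
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def frame_to_candidates(df: pd.DataFrame) -> list[PeptideCandidate]:
    return [
        PeptideCandidate(
            peptide=r.peptide, gene=r.gene, aa_change=r.aa_change, cls=r.cls,
            start_in_protein=int(r.start),
            mutated_offsets=tuple(int(x) for x in str(r.mutated_offsets).split(",") if x != ""),
            wt_peptide=getattr(r, "wt_peptide", "") or "",
        )
        for r in df.itertuples(index=False)
    ]


def write_candidates_tsv(candidates: list[PeptideCandidate], path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path) -> list[PeptideCandidate]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    return frame_to_candidates(df)
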