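"""Bisulfite-aware pairwise alignment against in-silico converted references.

The reference is converted assuming the fully unmethylated state, but every
position remembers what it was: plain A/G/T, a T that arose from a CpH
cytosine, or a T that arose from the C of a CpG site.  The substitution
contract of the aligner then encodes bisulfite chemistry:

* read T vs CpG-derived T  -> match (unmethylated molecule)
* read C vs CpG-derived T  -> match (methylated molecule)
* read T vs CpH-derived T  -> match (converted)
* read C vs CpH-derived T  -> match for scoring, but counted as a
  conversion failure by :func:`compute_conversion`
* everything else          -> standard match/mismatch

Alignment is global over the read with affine gap costs; gaps at the read's
3' end are free (reads may stop short of the amplicon end).  Ties in the
dynamic program break deterministically: diagonal, then up (read base over a
reference gap), then left.  Identity and CpH-conversion percentages and the
per-CpG methylation calls are pure functions of the resulting gapped pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import Locus

try:  # JIT-compiled DP; plain-Python fallback keeps the package importable
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "METH",
    "UNMETH",
    "MISSING",
    "GAP",
    "LBL_A",
    "LBL_G",
    "LBL_T",
    "LBL_T_CPH",
    "LBL_T_CPG",
    "AlignParams",
    "ConvertedReference",
    "BisulfiteAlignment",
    "convert_reference",
    "align_read",
    "align_batch",
    "compute_identity",
    "compute_conversion",
    "call_cpgs",
    "calls_to_string",
]

# per-CpG call codes
METH, UNMETH, MISSING = 1, 0, -1

# reference position labels
LBL_A, LBL_G, LBL_T, LBL_T_CPH, LBL_T_CPG = 0, 1, 2, 3, 4
GAP = -1

_LABEL_CHAR = {LBL_A: "A", LBL_G: "G", LBL_T: "T", LBL_T_CPH: "h", LBL_T_CPG: "g", GAP: "-"}

# read base codes
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = {0: "A", 1: "C", 2: "G", 3: "T", 4: "N", GAP: "-"}

# match table: rows read code (A,C,G,T,N), cols reference label
_MATCH = np.zeros((5, 5), dtype=np.bool_)
_MATCH[0, LBL_A] = True
_MATCH[2, LBL_G] = True
_MATCH[3, LBL_T] = True
_MATCH[3, LBL_T_CPH] = True
_MATCH[1, LBL_T_CPH] = True  # unconverted CpH: scored as match, flagged later
_MATCH[3, LBL_T_CPG] = True  # unmethylated CpG
_MATCH[1, LBL_T_CPG] = True  # methylated CpG


def encode_read(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring.  A gap of length k costs gap_open + (k-1)*gap_extend."""

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if not (self.gap_open <= 0.0 <= self.match_score):
            raise ValueError("need gap_open <= 0 <= match_score")
        if not (self.gap_extend <= 0.0):
            raise ValueError("gap_extend must be <= 0")
        if not (self.mismatch_score < self.match_score):
            raise ValueError("mismatch_score must be below match_score")


@dataclass(frozen=True)
class ConvertedReference:
    """In-silico bisulfite-converted reference for one locus.

    Covers only the alignable (post-primer) region.  ``labels`` classifies
    every position; ``cpg_ordinals`` maps alignable positions to the CpG
    ordinal they carry (-1 elsewhere).
    """

    locus_name: str
    labels: np.ndarray  # int8, alignable region only
    cpg_ordinals: np.ndarray  # intp, -1 where not a CpG-C position
    n_cpg: int

    @property
    def sequence(self) -> str:
        """Converted sequence with label annotation: h = T from CpH, g = T from CpG."""
        return "".join(_LABEL_CHAR[int(l)] for l in self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def convert_reference(locus: Locus) -> ConvertedReference:
    """Convert a locus: CpG-site C -> CpG-labelled T, other C -> CpH-labelled T,
    A/G/T keep themselves.  The primer region is excluded from alignment."""
    body = locus.sequence[locus.primer_len :]
    offset = locus.primer_len
    labels = np.empty(len(body), dtype=np.int8)
    ordinals = np.full(len(body), -1, dtype=np.intp)
    cpg_set = {p - offset: k for k, p in enumerate(locus.cpg_positions)}
    for i, b in enumerate(body):
        if b == "A":
            labels[i] = LBL_A
        elif b == "G":
            labels[i] = LBL_G
        elif b == "T":
            labels[i] = LBL_T
        elif i in cpg_set:
            labels[i] = LBL_T_CPG
            ordinals[i] = cpg_set[i]
        else:
            labels[i] = LBL_T_CPH
    return ConvertedReference(locus.name, labels, ordinals, locus.n_cpg)


_NEG = -1e30


@njit(cache=True)
def _affine_dp(read, ref, match_tab, match_s, mismatch_s, gap_open, gap_ext):
    """Affine-gap DP, global in the read, free gaps at the read's 3' end.

    Tie-break for the best cell state: diagonal, then up (consume read),
    then left (consume reference).  Returns (score, ops, n_ops, ref_end)
    where ops (reversed order) are 0=diag, 1=up, 2=left and ref_end is the
    last reference position consumed (exclusive).
    """
    n = read.shape[0]
    m = ref.shape[0]
    H = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in reference (consume read)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in read (consume reference)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    ptrIx = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 opened from H, 1 extended
    ptrIy = np.zeros((n + 1, m + 1), dtype=np.uint8)

    H[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_ext
        ptrIx[i, 0] = 0 if i == 1 else 1
        H[i, 0] = Ix[i, 0]
        ptrH[i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_ext
        ptrIy[0, j] = 0 if j == 1 else 1
        H[0, j] = Iy[0, j]
        ptrH[0, j] = 2

    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, m + 1):
            if match_tab[ri, ref[j - 1]]:
                sub = match_s
            else:
                sub = mismatch_s
            diag = H[i - 1, j - 1] + sub

            up_open = H[i - 1, j] + gap_open
            up_ext = Ix[i - 1, j] + gap_ext
            if up_open >= up_ext:
                Ix[i, j] = up_open
                ptrIx[i, j] = 0
            else:
                Ix[i, j] = up_ext
                ptrIx[i, j] = 1

            left_open = H[i, j - 1] + gap_open
            left_ext = Iy[i, j - 1] + gap_ext
            if left_open >= left_ext:
                Iy[i, j] = left_open
                ptrIy[i, j] = 0
            else:
                Iy[i, j] = left_ext
                ptrIy[i, j] = 1

            if diag >= Ix[i, j] and diag >= Iy[i, j]:
                H[i, j] = diag
                ptrH[i, j] = 0
            elif Ix[i, j] >= Iy[i, j]:
                H[i, j] = Ix[i, j]
                ptrH[i, j] = 1
            else:
                H[i, j] = Iy[i, j]
                ptrH[i, j] = 2

    # free end gaps on the read's 3' side: stop anywhere along the reference
    best_j = 0
    best = H[n, 0]
    for j in range(1, m + 1):
        if H[n, j] >= best:  # rightmost maximum -> align as much reference as possible
            best = H[n, j]
            best_j = j

    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i = n
    j = best_j
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            d = ptrH[i, j]
            if d == 0:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            else:
                state = d
        elif state == 1:
            frm = ptrIx[i, j]
            ops[k] = 1
            k += 1
            i -= 1
            state = 0 if frm == 0 else 1
        else:
            frm = ptrIy[i, j]
            ops[k] = 2
            k += 1
            j -= 1
            state = 0 if frm == 0 else 2
    return best, ops, k, best_j


@dataclass
class BisulfiteAlignment:
    """One read aligned to a converted reference.

    ``gapped_read`` / ``gapped_ref`` are parallel int8 arrays over the
    aligned span (reference positions beyond the read's 3' end are clipped,
    not gapped); -1 marks a gap.  ``gapped_ref_pos`` gives the alignable
    reference coordinate consumed in each column (-1 in reference gaps).
    """

    read_id: str
    gapped_read: np.ndarray
    gapped_ref: np.ndarray
    gapped_ref_pos: np.ndarray
    score: float
    reference: ConvertedReference
    identity_mode: str = "filtered"
    identity_pct: float = field(init=False)
    conversion_pct: float = field(init=False)
    cpg_calls: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.gapped_read.shape != self.gapped_ref.shape:
            raise ValueError("gapped read and reference differ in length")
        self.identity_pct = compute_identity(self, self.identity_mode)
        self.conversion_pct = compute_conversion(self)
        self.cpg_calls = call_cpgs(self)

    @property
    def gapped_read_str(self) -> str:
        return "".join(_CODE_BASE[int(c)] for c in self.gapped_read)

    @property
    def gapped_ref_str(self) -> str:
        return "".join(_LABEL_CHAR[int(l)] for l in self.gapped_ref)

    @property
    def calls_str(self) -> str:
        return calls_to_string(self.cpg_calls)


def calls_to_string(calls: Sequence[int]) -> str:
    return "".join("M" if c == METH else "U" if c == UNMETH else "." for c in calls)


def align_read(
    trimmed_read: str,
    converted_ref: ConvertedReference,
    params: AlignParams = AlignParams(),
    read_id: str = "",
    identity_mode: str = "filtered",
) -> BisulfiteAlignment:
    """Globally align a tag/primer-stripped read to a converted reference."""
    if not trimmed_read:
        raise ValueError("cannot align an empty read")
    read = encode_read(trimmed_read)
    score, ops, k, _ = _affine_dp(
        read,
        converted_ref.labels,
        _MATCH,
        float(params.match_score),
        float(params.mismatch_score),
        float(params.gap_open),
        float(params.gap_extend),
    )
    ops = ops[:k][::-1]  # traceback emitted tail-first
    ncol = ops.size
    g_read = np.full(ncol, GAP, dtype=np.int8)
    g_ref = np.full(ncol, GAP, dtype=np.int8)
    g_pos = np.full(ncol, -1, dtype=np.intp)
    consume_read = ops != 2
    consume_ref = ops != 1
    g_read[consume_read] = read[: consume_read.sum()]
    ref_idx = np.flatnonzero(consume_ref)
    g_ref[ref_idx] = converted_ref.labels[: ref_idx.size]
    g_pos[ref_idx] = np.arange(ref_idx.size)
    return BisulfiteAlignment(
        read_id=read_id,
        gapped_read=g_read,
        gapped_ref=g_ref,
        gapped_ref_pos=g_pos,
        score=float(score),
        reference=converted_ref,
        identity_mode=identity_mode,
    )


def compute_identity(aln: BisulfiteAlignment, mode: str = "filtered") -> float:
    """Percent identity over the aligned span.

    ``filtered`` (default): columns at CpG-derived positions are excluded
    (methylation state must not affect identity) and an unconverted CpH
    (read C over a CpH-derived T) counts as matched — it is penalised by the
    conversion filter instead.  ``all``: every column is eligible and an
    unconverted CpH counts as a mismatch, while C/T at CpG positions both
    still match (they are legitimate biological states).  Gap columns are
    eligible and unmatched in both modes.
    """
    r, f = aln.gapped_read, aln.gapped_ref
    both = (r != GAP) & (f != GAP)
    matched = np.zeros(r.shape, dtype=bool)
    matched[both] = _MATCH[r[both], f[both]]
    if mode == "filtered":
        eligible = f != LBL_T_CPG
    elif mode == "all":
        eligible = np.ones(r.shape, dtype=bool)
        matched = matched & ~((f == LBL_T_CPH) & (r == 1))  # unconverted CpH mismatches
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError("alignment has no identity-eligible columns")
    return 100.0 * float((matched & eligible).sum()) / n_eligible


def compute_conversion(aln: BisulfiteAlignment) -> float:
    """CpH conversion efficiency: share of CpH columns read as T among CpH
    columns read as C or T.  Columns with gaps or other bases are excluded;
    with no countable column the efficiency is 100.0 (no evidence of failure).
    """
    cph = aln.gapped_ref == LBL_T_CPH
    as_t = int((cph & (aln.gapped_read == 3)).sum())
    as_c = int((cph & (aln.gapped_read == 1)).sum())
    if as_t + as_c == 0:
        return 100.0
    return 100.0 * as_t / (as_t + as_c)


def call_cpgs(aln: BisulfiteAlignment) -> np.ndarray:
    """Per-CpG calls over the locus: read C -> METH, read T -> UNMETH,
    gap/other base/not covered -> MISSING.  One call per CpG ordinal."""
    calls = np.full(aln.reference.n_cpg, MISSING, dtype=np.int8)
    at_cpg = aln.gapped_ref == LBL_T_CPG
    for col in np.flatnonzero(at_cpg):
        ordinal = aln.reference.cpg_ordinals[aln.gapped_ref_pos[col]]
        b = aln.gapped_read[col]
        if b == 1:
            calls[ordinal] = METH
        elif b == 3:
            calls[ordinal] = UNMETH
    return calls


def align_batch(
    bins: dict[tuple[str, str], list[tuple[str, str]]],
    loci,
    params: AlignParams = AlignParams(),
    identity_mode: str = "filtered",
) -> pd.DataFrame:
    """Align demultiplexed reads bin by bin.

    ``bins`` maps (sample, locus_name) -> [(read_id, trimmed_seq), ...] as
    produced by :meth:`DemuxResult.bin_reads`; ``loci`` is an iterable of
    :class:`Locus` or a mapping name -> Locus.  Returns the per-read metrics
    table (read_id, sample, locus, score, identity_pct, conversion_pct,
    calls) consumed by the quantification stage.
    """
    if not isinstance(loci, dict):
        loci = {loc.name: loc for loc in loci}
    refs = {name: convert_reference(loc) for name, loc in loci.items()}
    rows = []
    for (sample, locus_name), reads in sorted(bins.items()):
        ref = refs[locus_name]
        for read_id, seq in reads:
            if not seq:
                rows.append(
                    {
                        "read_id": read_id,
                        "sample": sample,
                        "locus": locus_name,
                        "score": float("nan"),
                        "identity_pct": 0.0,
                        "conversion_pct": 100.0,
                        "calls": "." * ref.n_cpg,
                    }
                )
                continue
            aln = align_read(seq, ref, params, read_id=read_id, identity_mode=identity_mode)
            rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "locus": locus_name,
                    "score": aln.score,
                    "identity_pct": aln.identity_pct,
                    "conversion_pct": aln.conversion_pct,
                    "calls": aln.calls_str,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["read_id", "sample", "locus", "score", "identity_pct", "conversion_pct", "calls"],
    )
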