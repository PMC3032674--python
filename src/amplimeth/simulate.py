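"""Synthetic 454-style bisulfite amplicon reads with known ground truth.

This module emulates the statistical structure of a multiplexed GS FLX
bisulfite amplicon run: each read carries a 9-10 nt sample tag, a
locus-specific forward primer, and the bisulfite-converted body of a single
template molecule.  Molecules are drawn from a three-component epiallele
mixture (fully methylated / fully unmethylated / heterogeneous), conversion
of unmethylated cytosines may fail at a small per-base rate, and sequencing
errors comprise per-base substitutions plus homopolymer indels (deletion
biased, the dominant 454 error mode).  Matched "bulk pyrosequencing"
measurements are simulated as the true per-CpG levels plus Gaussian noise.

Every generated molecule's pattern is recorded, so downstream recovery of
per-CpG levels and epiallele fractions can be checked against exact truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MID_TAGS",
    "Locus",
    "EpiallelePatternModel",
    "ErrorModel",
    "SimulationTruth",
    "SimulationRun",
    "build_locus",
    "sample_epialleles",
    "bisulfite_convert_molecule",
    "apply_read_errors",
    "simulate_run",
    "simulate_pyro",
]

#: Ten sample tags (9-10 nt), pairwise Hamming distance >= 4 on the common
#: prefix, no homopolymer of length 3+.  Fixed sequences so runs are
#: reproducible; real 454 MID sets are proprietary but have the same shape.
MID_TAGS: tuple[str, ...] = (
    "TTCCTACGTC",
    "TTCGTACAGA",
    "TTGGCATTGA",
    "TTAGGAATCA",
    "TCAATTGAGA",
    "GTACGTCGT",
    "CATGATTGT",
    "GCCATGCTT",
    "GGCTGTAAT",
    "TAATACGAGC",
)

_A, _C, _G, _T = ord("A"), ord("C"), ord("G"), ord("T")


def _rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Locus:
    """A reference amplicon: genomic (unconverted) sequence with annotated
    CpG sites and the extent of the locus-specific forward primer.

    ``cpg_positions`` are 0-based indices of the C of each CpG, all within
    the post-primer body of the amplicon.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]
    primer_len: int

    def __post_init__(self):
        seq = self.sequence
        if not (100 <= len(seq) <= 350):
            raise ValueError(
                f"locus {self.name}: length {len(seq)} outside the supported "
                "amplicon range 100-350 bp"
            )
        if set(seq) - set("ACGT"):
            raise ValueError(f"locus {self.name}: sequence must be uppercase A/C/G/T")
        pos = tuple(self.cpg_positions)
        object.__setattr__(self, "cpg_positions", pos)
        if any(b >= a for a, b in zip(pos[1:], pos)):
            raise ValueError(f"locus {self.name}: cpg_positions must be strictly increasing")
        for p in pos:
            if not (self.primer_len <= p <= len(seq) - 2):
                raise ValueError(f"locus {self.name}: CpG at {p} outside alignable range")
            if seq[p] != "C" or seq[p + 1] != "G":
                raise ValueError(f"locus {self.name}: position {p} is not a CpG")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def primer(self) -> str:
        """Genomic (unconverted) forward-primer region."""
        return self.sequence[: self.primer_len]

    @property
    def converted_primer(self) -> str:
        """Forward primer as synthesised for bisulfite PCR: every C -> T."""
        return self.primer.replace("C", "T")

    @classmethod
    def from_sequence(cls, name: str, sequence: str, primer_len: int) -> "Locus":
        """Build a locus by scanning the genomic sequence for CpG dinucleotides
        downstream of the primer."""
        sequence = sequence.upper()
        pos = tuple(
            i
            for i in range(primer_len, len(sequence) - 1)
            if sequence[i] == "C" and sequence[i + 1] == "G"
        )
        return cls(name, sequence, pos, primer_len)


@dataclass(frozen=True)
class EpiallelePatternModel:
    """Mixture over single-molecule methylation patterns.

    A molecule is fully methylated with probability ``p_full``, fully
    unmethylated with ``p_none``, otherwise each CpG is an independent
    Bernoulli(``site_probs[i]``).  Captures the spectrum from dichotomous
    (all-or-nothing) to heterogeneous epiallele populations.
    """

    p_full: float
    p_none: float
    site_probs: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "site_probs", tuple(float(p) for p in self.site_probs))
        probs = (self.p_full, self.p_none, *self.site_probs)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_full + self.p_none > 1.0 + 1e-12:
            raise ValueError("p_full + p_none must not exceed 1")

    @property
    def n_cpg(self) -> int:
        return len(self.site_probs)


@dataclass(frozen=True)
class ErrorModel:
    """Per-read error process.

    conversion_failure_rate
        probability an unmethylated C survives bisulfite conversion (per C).
    substitution_rate
        per-base miscall probability.
    hp_indel_base_rate
        per-homopolymer indel probability multiplier; a run of length L >= 2
        receives an indel with probability ``min(1, rate * (L - 1))``.
    deletion_bias
        fraction of homopolymer indels that are deletions (454 errors are
        deletion dominated).
    """

    conversion_failure_rate: float = 0.005
    substitution_rate: float = 0.002
    hp_indel_base_rate: float = 0.01
    deletion_bias: float = 0.8

    def __post_init__(self):
        for name in ("conversion_failure_rate", "substitution_rate",
                     "hp_indel_base_rate", "deletion_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated run.

    molecules: one row per molecule (sample, locus, read_id, pattern string
    over {1,0}).  levels: one row per sample x locus x CpG with the realised
    true level in percent (column mean of the pattern matrix x 100).
    read_counts: reads emitted per sample x locus bin.
    """

    molecules: pd.DataFrame
    levels: pd.DataFrame
    read_counts: pd.DataFrame

    def pattern_matrix(self, sample: str, locus: str) -> np.ndarray:
        sub = self.molecules[
            (self.molecules["sample"] == sample) & (self.molecules["locus"] == locus)
        ]
        return np.array([[int(c) for c in p] for p in sub["pattern"]], dtype=np.int8)


@dataclass
class SimulationRun:
    reads: list[tuple[str, str]]  # (read_id, sequence) in emitted order
    records: list  # TaggedPrimerRecord, one per sample x locus bin
    loci: list[Locus]
    truth: SimulationTruth


def build_locus(
    name: str,
    length: int,
    n_cpg: int,
    gc_fraction: float = 0.5,
    seed=None,
    primer_len: int = 20,
) -> Locus:
    """Generate a random amplicon reference.

    The sequence contains CpG dinucleotides exactly at the generated
    ``cpg_positions`` (never elsewhere: during base sampling a G is never
    placed after a C, with the blocked G mass redirected to C so the marginal
    G+C fraction stays at ``gc_fraction``).  At least one homopolymer run of
    length >= 4 is guaranteed so homopolymer-error handling is exercised.
    """
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must be in (0, 1)")
    if length < primer_len + 2 * n_cpg + 2:
        raise ValueError(
            f"cannot place {n_cpg} CpGs in a {length} bp amplicon with a "
            f"{primer_len} bp primer"
        )
    rng = _rng(seed)

    half_gc = gc_fraction / 2.0
    half_at = (1.0 - gc_fraction) / 2.0
    base_probs = np.array([half_at, half_gc, half_gc, half_at])  # A C G T
    after_c_probs = np.array([half_at, gc_fraction, 0.0, half_at])  # no G after C

    seq = np.empty(length, dtype=np.uint8)
    alphabet = np.array([_A, _C, _G, _T], dtype=np.uint8)
    prev_c = False
    for i in range(length):
        p = after_c_probs if prev_c else base_probs
        b = rng.choice(4, p=p)
        seq[i] = alphabet[b]
        prev_c = b == 1

    # CpG placement: n_cpg starts in [primer_len, length-2], consecutive
    # starts >= 2 apart (sites may be back-to-back CGCG but never overlap).
    span = length - 2 - primer_len + 1
    free = span - (n_cpg - 1)
    picks = np.sort(rng.choice(free, size=n_cpg, replace=False))
    cpg_positions = tuple(int(primer_len + picks[i] + i) for i in range(n_cpg))
    for p in cpg_positions:
        seq[p] = _C
        seq[p + 1] = _G

    # Forced edits may have left a C immediately before a site C (fine) but a
    # C placed right before a forced... scan defensively for stray CGs and
    # break them (G -> C keeps GC content; rescan handles cascades).
    site_set = set(cpg_positions)
    i = 0
    while i < length - 1:
        if seq[i] == _C and seq[i + 1] == _G and i not in site_set:
            seq[i + 1] = _C
        else:
            i += 1

    # guarantee a homopolymer run >= 4 (A-run survives bisulfite conversion)
    s = seq.tobytes().decode()
    if not _has_run(s, 4):
        blocked = set()
        for p in cpg_positions:
            blocked.update(range(p - 3, p + 2))
        candidates = [
            w
            for w in range(0, length - 4)
            if not any(j in blocked for j in range(w, w + 4))
        ]
        if candidates:  # pathological CpG-dense loci keep their sequence as-is
            w = int(rng.choice(candidates))
            seq[w : w + 4] = _A
            s = seq.tobytes().decode()

    return Locus(name, s, cpg_positions, primer_len)


def _has_run(s: str, k: int) -> bool:
    return any(len(list(g)) >= k for _, g in itertools.groupby(s))


def sample_epialleles(
    model: EpiallelePatternModel, n_molecules: int, seed=None
) -> np.ndarray:
    """Draw an ``n_molecules x n_cpg`` binary pattern matrix from the mixture."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = _rng(seed)
    k = model.n_cpg
    u = rng.random(n_molecules)
    het = rng.random((n_molecules, k)) < np.asarray(model.site_probs)
    mat = het.astype(np.int8)
    mat[u < model.p_full] = 1
    mat[(u >= model.p_full) & (u < model.p_full + model.p_none)] = 0
    return mat


def bisulfite_convert_molecule(
    locus: Locus, pattern: Sequence[int], error_model: ErrorModel, seed=None
) -> str:
    """Bisulfite-convert one template molecule (forward strand).

    Every genomic C at a CpG whose pattern bit is 1 stays C; every other C
    (CpH, and unmethylated CpG) deaminates to T, except that with probability
    ``conversion_failure_rate`` it survives unconverted.
    """
    pattern = np.asarray(pattern, dtype=np.int8)
    if pattern.shape != (locus.n_cpg,):
        raise ValueError(
            f"pattern length {pattern.size} != {locus.n_cpg} CpGs of {locus.name}"
        )
    rng = _rng(seed)
    codes = np.frombuffer(locus.sequence.encode(), dtype=np.uint8).copy()
    methylated = np.zeros(codes.size, dtype=bool)
    pos = np.asarray(locus.cpg_positions, dtype=np.intp)
    methylated[pos[pattern == 1]] = True
    c_mask = codes == _C
    survives = rng.random(codes.size) < error_model.conversion_failure_rate
    codes[c_mask & ~methylated & ~survives] = _T
    return codes.tobytes().decode()


def _homopolymer_runs(s: str) -> list[tuple[int, int]]:
    """Maximal homopolymer runs as (start, length), length >= 2."""
    runs = []
    i = 0
    n = len(s)
    while i < n:
        j = i + 1
        while j < n and s[j] == s[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


def apply_read_errors(sequence: str, error_model: ErrorModel, seed=None) -> str:
    """Apply 454-style sequencing errors to one read.

    Homopolymer runs (length L >= 2, identified on the input sequence) each
    receive an indel with probability ``min(1, hp_indel_base_rate*(L-1))`` —
    a single-base deletion with probability ``deletion_bias``, else a
    single-base insertion.  Substitutions hit every base independently at
    ``substitution_rate``.
    """
    rng = _rng(seed)
    n = len(sequence)
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()

    if error_model.substitution_rate > 0.0 and n:
        hit = np.flatnonzero(rng.random(n) < error_model.substitution_rate)
        for i in hit:
            others = [b for b in (_A, _C, _G, _T) if b != codes[i]]
            codes[i] = others[rng.integers(3)]

    edits = []  # (position, +1 insert / -1 delete)
    if error_model.hp_indel_base_rate > 0.0:
        for start, L in _homopolymer_runs(sequence):
            p = min(1.0, error_model.hp_indel_base_rate * (L - 1))
            if rng.random() < p:
                where = start + int(rng.integers(L))
                is_del = rng.random() < error_model.deletion_bias
                edits.append((where, -1 if is_del else +1))

    out = codes.tolist()
    for where, kind in sorted(edits, reverse=True):
        if kind < 0:
            del out[where]
        else:
            out.insert(where, out[where])
    return bytes(out).decode()


def simulate_run(
    loci: Sequence[Locus],
    samples: Sequence[str],
    pattern_models,
    error_model: ErrorModel,
    reads_per_bin,
    seed=None,
    tags: Sequence[str] | None = None,
    shuffle: bool = True,
) -> SimulationRun:
    """Simulate one multiplexed amplicon run.

    Parameters
    ----------
    pattern_models
        a single :class:`EpiallelePatternModel` used for every bin, or a
        mapping ``(sample, locus_name) -> model``.
    reads_per_bin
        an int, or a mapping ``(sample, locus_name) -> int``.
    tags
        one tag per sample; defaults to the packaged :data:`MID_TAGS`.

    Each read is ``tag + bisulfite-converted amplicon`` passed through the
    sequencing error model; the primer region converts like the rest of the
    template (primer synthesis errors are not modelled separately).
    Returns the reads, the tag/primer table and exact per-molecule truth.
    """
    from .demultiplex import TaggedPrimerRecord  # avoid import cycle at top

    samples = list(samples)
    if tags is None:
        if len(samples) > len(MID_TAGS):
            raise ValueError(
                f"only {len(MID_TAGS)} packaged tags; supply custom tags for "
                f"{len(samples)} samples"
            )
        tags = MID_TAGS[: len(samples)]
    tags = [str(t) for t in tags]
    if len(tags) != len(samples):
        raise ValueError("need exactly one tag per sample")
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate sample tags")

    records = [
        TaggedPrimerRecord(s, loc.name, tag, loc.converted_primer)
        for s, tag in zip(samples, tags)
        for loc in loci
    ]
    if len({(r.tag, r.primer) for r in records}) != len(records):
        raise ValueError("duplicate (tag, primer) combinations across records")

    def model_for(sample, locus):
        if isinstance(pattern_models, Mapping):
            return pattern_models[(sample, locus.name)]
        return pattern_models

    def n_for(sample, locus):
        if isinstance(reads_per_bin, Mapping):
            return int(reads_per_bin[(sample, locus.name)])
        return int(reads_per_bin)

    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    bin_seeds = root.spawn(len(samples) * len(loci) + 1)

    reads: list[tuple[str, str]] = []
    mol_rows = []
    level_rows = []
    count_rows = []
    b = 0
    for sample, tag in zip(samples, tags):
        for locus in loci:
            rng = np.random.default_rng(bin_seeds[b])
            b += 1
            n = n_for(sample, locus)
            model = model_for(sample, locus)
            if model.n_cpg != locus.n_cpg:
                raise ValueError(
                    f"model has {model.n_cpg} site probabilities but locus "
                    f"{locus.name} has {locus.n_cpg} CpGs"
                )
            patterns = sample_epialleles(model, max(n, 1), rng)[:n]
            for i in range(n):
                read_id = f"{sample}:{locus.name}:{i:05d}"
                body = bisulfite_convert_molecule(locus, patterns[i], error_model, rng)
                read = apply_read_errors(tag + body, error_model, rng)
                reads.append((read_id, read))
                mol_rows.append(
                    {
                        "sample": sample,
                        "locus": locus.name,
                        "read_id": read_id,
                        "pattern": "".join(str(int(x)) for x in patterns[i]),
                    }
                )
            count_rows.append({"sample": sample, "locus": locus.name, "n_reads": n})
            if n > 0:
                # same arithmetic order as the quantifier (100*k/n), so exact
                # error-free recovery is bitwise exact
                true_levels = 100.0 * patterns.sum(axis=0) / n
                for k, lv in enumerate(true_levels):
                    level_rows.append(
                        {
                            "sample": sample,
                            "locus": locus.name,
                            "cpg_index": k,
                            "true_level_pct": float(lv),
                        }
                    )

    if shuffle:
        order = np.random.default_rng(bin_seeds[-1]).permutation(len(reads))
        reads = [reads[i] for i in order]

    truth = SimulationTruth(
        molecules=pd.DataFrame(mol_rows, columns=["sample", "locus", "read_id", "pattern"]),
        levels=pd.DataFrame(
            level_rows, columns=["sample", "locus", "cpg_index", "true_level_pct"]
        ),
        read_counts=pd.DataFrame(count_rows, columns=["sample", "locus", "n_reads"]),
    )
    return SimulationRun(reads=reads, records=records, loci=list(loci), truth=truth)


def simulate_pyro(truth_levels: pd.DataFrame, noise_sd: float, seed=None) -> pd.DataFrame:
    """Simulate bulk pyrosequencing of the same templates.

    Adds independent Gaussian noise (SD ``noise_sd`` percentage points,
    emulating the 2-10 point technical variability of the bulk assay) to each
    true per-CpG level and clips to [0, 100].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    levels = truth_levels["true_level_pct"].to_numpy(dtype=float)
    if ((levels < 0) | (levels > 100)).any():
        raise ValueError("true levels must lie in [0, 100]")
    rng = _rng(seed)
    noisy = np.clip(levels + rng.normal(0.0, noise_sd, size=levels.size), 0.0, 100.0)
    out = truth_levels[["sample", "locus", "cpg_index"]].copy()
    out["level_pct"] = noisy
    return out
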