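"""Unit, property and oracle tests for bisulfite-aware alignment."""

from types import SimpleNamespace

import numpy as np
import pytest

from amplimeth import (
    METH,
    MISSING,
    UNMETH,
    AlignParams,
    ErrorModel,
    align_read,
    bisulfite_convert_molecule,
    build_locus,
    call_cpgs,
    compute_conversion,
    compute_identity,
    convert_reference,
)
from amplimeth.align import (
    GAP,
    LBL_A,
    LBL_G,
    LBL_T,
    LBL_T_CPG,
    LBL_T_CPH,
    BisulfiteAlignment,
    ConvertedReference,
    encode_read,
)

from ._oracle import bruteforce_best_score

_CHAR_TO_LABEL = {"A": LBL_A, "G": LBL_G, "T": LBL_T, "h": LBL_T_CPH, "g": LBL_T_CPG}


def dp_score(read: str, ref_str: str, params: AlignParams = AlignParams()) -> float:
    """Score from the dynamic program alone (no metric computation)."""
    from amplimeth.align import _MATCH, _affine_dp

    labels = np.array([_CHAR_TO_LABEL[c] for c in ref_str], dtype=np.int8)
    score, _, _, _ = _affine_dp(
        encode_read(read),
        labels,
        _MATCH,
        float(params.match_score),
        float(params.mismatch_score),
        float(params.gap_open),
        float(params.gap_extend),
    )
    return float(score)


def toy_reference(labels, ordinals=None):
    labels = np.asarray(labels, dtype=np.int8)
    if ordinals is None:
        ordinals = np.full(labels.size, -1, dtype=np.intp)
        k = 0
        for i in np.flatnonzero(labels == LBL_T_CPG):
            ordinals[i] = k
            k += 1
    n_cpg = int((np.asarray(ordinals) >= 0).sum())
    return ConvertedReference("toy", labels, np.asarray(ordinals, dtype=np.intp), n_cpg)


def manual_alignment(read_str, ref_labels, ref=None):
    """Build a BisulfiteAlignment directly from a gapped pair ('-' = gap)."""
    labels = np.array(
        [GAP if c == "-" else c for c in ref_labels], dtype=np.int8
    )
    if ref is None:
        ref = toy_reference(labels[labels != GAP])
    g_read = np.array(
        [GAP if c == "-" else {"A": 0, "C": 1, "G": 2, "T": 3}.get(c, 4) for c in read_str],
        dtype=np.int8,
    )
    g_pos = np.full(labels.size, -1, dtype=np.intp)
    g_pos[labels != GAP] = np.arange(int((labels != GAP).sum()))
    return BisulfiteAlignment("toy_read", g_read, labels, g_pos, 0.0, ref)


class TestConvertReference:
    def test_label_rule_on_toy_sequence(self):
        # ACGTCA with a CpG at 1 and no primer
        loc = SimpleNamespace(
            name="toy", sequence="ACGTCA", primer_len=0, cpg_positions=(1,), n_cpg=1
        )
        ref = convert_reference(loc)
        assert list(ref.labels) == [LBL_A, LBL_T_CPG, LBL_G, LBL_T, LBL_T_CPH, LBL_A]
        assert ref.sequence == "AgGThA"

    def test_no_cytosine_means_no_converted_labels(self):
        loc = SimpleNamespace(
            name="toy", sequence="ATGTAGGATT", primer_len=0, cpg_positions=(), n_cpg=0
        )
        ref = convert_reference(loc)
        assert not ((ref.labels == LBL_T_CPH) | (ref.labels == LBL_T_CPG)).any()

    def test_cpg_label_count_matches_locus(self):
        for seed in range(5):
            loc = build_locus("L", 160, 6, 0.5, seed=seed)
            ref = convert_reference(loc)
            assert int((ref.labels == LBL_T_CPG).sum()) == loc.n_cpg
            # CpH label count equals non-site cytosines in the alignable body
            body = loc.sequence[loc.primer_len :]
            n_cph = body.count("C") - loc.n_cpg
            assert int((ref.labels == LBL_T_CPH).sum()) == n_cph


class TestAlignRead:
    def test_unmethylated_identity_case(self, locus, converted, error_free):
        read = bisulfite_convert_molecule(locus, [0] * locus.n_cpg, error_free, 0)
        aln = align_read(read[locus.primer_len :], converted)
        assert aln.identity_pct == 100.0
        assert aln.conversion_pct == 100.0
        assert (aln.cpg_calls == UNMETH).all()
        assert aln.score == len(converted) * 1.0

    def test_methylated_identity_case(self, locus, converted, error_free):
        read = bisulfite_convert_molecule(locus, [1] * locus.n_cpg, error_free, 0)
        aln = align_read(read[locus.primer_len :], converted)
        assert aln.identity_pct == 100.0
        assert aln.conversion_pct == 100.0
        assert (aln.cpg_calls == METH).all()

    def test_truncated_read_free_end_gap(self, locus, converted, error_free):
        read = bisulfite_convert_molecule(locus, [0] * locus.n_cpg, error_free, 0)
        short = read[locus.primer_len : locus.primer_len + 90]
        aln = align_read(short, converted)
        assert aln.score == 90.0  # no end-gap penalty
        assert aln.identity_pct == 100.0
        uncovered = [p for p in locus.cpg_positions if p - locus.primer_len >= 90]
        assert int((aln.cpg_calls == MISSING).sum()) == len(uncovered)

    def test_empty_read_raises(self, converted):
        with pytest.raises(ValueError):
            align_read("", converted)

    def test_deterministic_tie_breaking(self, converted, locus, error_free):
        read = bisulfite_convert_molecule(locus, [0] * locus.n_cpg, error_free, 0)
        read = read[locus.primer_len :]
        mangled = read[:40] + read[41:]  # one deletion
        a = align_read(mangled, converted)
        b = align_read(mangled, converted)
        assert a.gapped_read_str == b.gapped_read_str
        assert a.gapped_ref_str == b.gapped_ref_str

    def test_homopolymer_deletion_costs_one_column(self, error_free):
        loc = build_locus("L", 150, 4, 0.5, seed=17)
        ref = convert_reference(loc)
        clean = bisulfite_convert_molecule(loc, [0] * 4, error_free, 0)[loc.primer_len :]
        # delete one base from a homopolymer run (>= 4) not touching a CpG column
        pos = None
        i = 0
        while i < len(clean):
            j = i
            while j < len(clean) and clean[j] == clean[i]:
                j += 1
            if j - i >= 4 and not (ref.labels[i:j] == LBL_T_CPG).any():
                pos = i
                break
            i = j
        assert pos is not None, "locus lacks a CpG-free homopolymer run"
        mangled = clean[:pos] + clean[pos + 1 :]
        base = align_read(clean, ref)
        aln = align_read(mangled, ref)
        n_eligible = int((base.gapped_ref != LBL_T_CPG).sum())
        assert aln.identity_pct == pytest.approx(100.0 * (n_eligible - 1) / n_eligible)
        changed = (aln.cpg_calls != base.cpg_calls).sum()
        assert changed <= 1
        if changed:
            assert (aln.cpg_calls[aln.cpg_calls != base.cpg_calls] == MISSING).all()


class TestDPOracle:
    def test_dp_equals_bruteforce_on_small_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(400):
            n = int(rng.integers(1, 11))
            m = int(rng.integers(1, 11))
            read = "".join(rng.choice(list("ACGT"), n))
            ref_str = "".join(rng.choice(list("AGThg"), m))
            got = dp_score(read, ref_str)
            want = bruteforce_best_score(read, ref_str)
            assert got == pytest.approx(want), (read, ref_str)

    def test_dp_with_nondefault_params(self):
        rng = np.random.default_rng(7)
        params = AlignParams(2.0, -3.0, -5.0, -0.5)
        for _ in range(100):
            read = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 9))))
            ref_str = "".join(rng.choice(list("AGThg"), int(rng.integers(1, 9))))
            got = dp_score(read, ref_str, params)
            want = bruteforce_best_score(read, ref_str, 2.0, -3.0, -5.0, -0.5)
            assert got == pytest.approx(want)


class TestIdentity:
    def test_perfect_alignment(self):
        aln = manual_alignment("ATGT", [LBL_A, LBL_T, LBL_G, LBL_T_CPH])
        assert compute_identity(aln) == 100.0

    def test_one_mismatch_in_ten(self):
        labels = [LBL_A] * 10
        aln = manual_alignment("AAAAAAAAAG", labels)
        assert compute_identity(aln) == 90.0

    def test_gap_column_counts_against_identity(self):
        aln = manual_alignment("A-AA", [LBL_A, LBL_A, LBL_A, LBL_A])
        assert compute_identity(aln) == 75.0

    def test_unconverted_cph_forgiven_by_default(self):
        aln = manual_alignment("AC", [LBL_A, LBL_T_CPH])
        assert compute_identity(aln) == 100.0
        assert compute_identity(aln, mode="all") == 50.0

    def test_identity_invariant_to_methylation_state(self, rng):
        for _ in range(30):
            m = int(rng.integers(4, 15))
            labels = rng.choice([LBL_A, LBL_G, LBL_T, LBL_T_CPH, LBL_T_CPG], m)
            read = [
                "C" if l == LBL_T_CPG and rng.random() < 0.5 else "TAGT"[int(rng.integers(4))]
                for l in labels
            ]
            aln = manual_alignment("".join(read), labels)
            flipped = [
                ("T" if c == "C" else "C") if l == LBL_T_CPG else c
                for c, l in zip(read, labels)
            ]
            aln2 = manual_alignment("".join(flipped), labels)
            assert compute_identity(aln) == compute_identity(aln2)

    def test_zero_eligible_columns_raises(self):
        with pytest.raises(ValueError):
            manual_alignment("T", [LBL_T_CPG])  # identity computed on construction


class TestConversion:
    def test_all_converted(self):
        aln = manual_alignment("TTT", [LBL_T_CPH] * 3)
        assert compute_conversion(aln) == 100.0

    def test_one_unconverted_of_twenty(self):
        aln = manual_alignment("C" + "T" * 19, [LBL_T_CPH] * 20)
        assert compute_conversion(aln) == 95.0

    def test_no_cph_evidence_means_full_efficiency(self):
        aln = manual_alignment("AG", [LBL_A, LBL_G])
        assert compute_conversion(aln) == 100.0

    def test_mean_conversion_tracks_failure_rate(self, locus):
        f = 0.02
        em = ErrorModel(f, 0, 0, 0)
        ref = convert_reference(locus)
        rng = np.random.default_rng(31)
        convs = []
        for _ in range(300):
            read = bisulfite_convert_molecule(locus, [0] * locus.n_cpg, em, rng)
            convs.append(align_read(read[locus.primer_len :], ref).conversion_pct)
        assert abs(np.mean(convs) - 100 * (1 - f)) < 0.5


class TestCallCpgs:
    def test_gap_at_cpg_is_missing(self):
        aln = manual_alignment("A-A", [LBL_A, LBL_T_CPG, LBL_A])
        assert list(aln.cpg_calls) == [MISSING]

    def test_foreign_base_at_cpg_is_missing(self):
        aln = manual_alignment("AAA", [LBL_A, LBL_T_CPG, LBL_A])
        assert list(aln.cpg_calls) == [MISSING]

    def test_calls_recover_simulated_pattern(self, locus, converted, error_free, rng):
        for _ in range(20):
            pattern = rng.integers(0, 2, locus.n_cpg)
            read = bisulfite_convert_molecule(locus, pattern, error_free, rng)
            aln = align_read(read[locus.primer_len :], converted)
            np.testing.assert_array_equal(aln.cpg_calls, pattern)
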