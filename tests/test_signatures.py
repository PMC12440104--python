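import itertools

import numpy as np
import pandas as pd
import pytest
from helpers import make_variant, variants_frame
from scipy import stats

from pgin.exceptions import ChannelOrderError, DegenerateInputError, FormatError
from pgin.signatures import (
    CHANNELS,
    MutationCatalog,
    SignatureSet,
    build_catalog,
    cosine_similarity_matrix,
    correlate_contribution_burden,
    extract_signatures,
    group_contributions,
    match_to_reference,
    snv_channel,
)
from pgin.synthetic_cohort import simulate_catalog, simulate_cohort_catalog


class TestChannels:
    def test_cosmic_order(self):
        assert len(CHANNELS) == 96
        assert CHANNELS[0] == "A[C>A]A" and CHANNELS[15] == "T[C>A]T"
        assert CHANNELS[16] == "A[C>G]A" and CHANNELS[-1] == "T[T>G]T"

    def test_pyrimidine_channel_direct(self):
        assert snv_channel("C", "A", "A", "A") == "A[C>A]A"

    def test_purine_reverse_complement(self):
        # G>T with flanks (T, G) is C>A with flanks (C, A) on the other strand
        assert snv_channel("G", "T", "T", "G") == "C[C>A]A"

    def test_non_acgt_base_raises(self):
        with pytest.raises(FormatError):
            snv_channel("C", "A", "N", "A")


class TestBuildCatalog:
    def test_single_snv_lands_in_channel(self):
        df = variants_frame([make_variant(ref="C", alt="A", context5="A", context3="A")])
        cat = build_catalog(df)
        assert cat.counts[CHANNELS.index("A[C>A]A"), 0] == 1
        assert cat.counts.sum() == 1

    def test_column_sum_conserves_context_complete_snvs(self, rng):
        rows = []
        for i in range(100):
            ch = CHANNELS[rng.integers(96)]
            c5, sub, c3 = ch[0], ch[2:5], ch[-1]
            ref, alt = sub.split(">")
            rows.append(make_variant(pos=100 + i, ref=ref, alt=alt, context5=c5, context3=c3))
        cat = build_catalog(variants_frame(rows))
        assert cat.counts[:, 0].sum() == 100

    def test_missing_context_dropped(self):
        rows = [
            make_variant(ref="C", alt="A"),
            make_variant(pos=200, ref="C", alt="A", context5=None),
        ]
        assert build_catalog(variants_frame(rows)).counts.sum() == 1

    def test_strand_flip_involution(self, rng):
        """Complementing every SNV's reported strand leaves the catalog unchanged."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rows, flipped = [], []
        for i in range(50):
            ch = CHANNELS[rng.integers(96)]
            c5, sub, c3 = ch[0], ch[2:5], ch[-1]
            ref, alt = sub.split(">")
            rows.append(make_variant(pos=100 + i, ref=ref, alt=alt, context5=c5, context3=c3))
            flipped.append(
                make_variant(
                    pos=100 + i,
                    ref=comp[ref],
                    alt=comp[alt],
                    context5=comp[c3],
                    context3=comp[c5],
                )
            )
        a = build_catalog(variants_frame(rows)).counts
        b = build_catalog(variants_frame(flipped)).counts
        assert (a == b).all()


class TestSimulateCatalog:
    def test_pure_signature_law_of_large_numbers(self, reference):
        mix = np.zeros(len(reference.labels))
        mix[2] = 1.0  # the C>A-concentrated analog
        col = simulate_catalog(mix, 10_000, reference, seed=5)
        emp = col / col.sum()
        assert np.max(np.abs(emp - reference.signatures[2])) < 0.01

    def test_zero_mutations_all_zero(self, reference):
        mix = np.zeros(len(reference.labels))
        mix[0] = 1.0
        assert simulate_catalog(mix, 0, reference, seed=1).sum() == 0

    def test_disjoint_support_split_within_binomial_ci(self):
        a = np.zeros(96)
        a[:48] = 1 / 48
        b = np.zeros(96)
        b[48:] = 1 / 48
        ref = SignatureSet(signatures=np.vstack([a, b]), labels=["A", "B"])
        n = 4000
        col = simulate_catalog([0.5, 0.5], n, ref, seed=3)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.5)
        assert lo <= col[:48].sum() <= hi


class TestExtract:
    def test_single_signature_recovery(self, reference):
        mixes = np.tile([1.0, 0, 0, 0], (20, 1))
        cat = simulate_cohort_catalog(mixes, 2000, reference, seed=9)
        sigs = extract_signatures(cat, rank=1, seed=0, n_restarts=5)
        cos = cosine_similarity_matrix(sigs.signatures, reference.signatures[:1])[0, 0]
        assert cos >= 0.99

    def test_determinism_given_seed(self, reference):
        mixes = np.tile([0.5, 0.3, 0.2, 0.0], (10, 1))
        cat = simulate_cohort_catalog(mixes, 500, reference, seed=2)
        s1 = extract_signatures(cat, rank=2, seed=7, n_restarts=3)
        s2 = extract_signatures(cat, rank=2, seed=7, n_restarts=3)
        assert np.array_equal(s1.signatures, s2.signatures)
        assert np.array_equal(s1.exposures, s2.exposures)

    def test_zero_catalog_is_degenerate(self):
        cat = MutationCatalog(counts=np.zeros((96, 4), dtype=int), sample_ids=list("abcd"))
        with pytest.raises(DegenerateInputError):
            extract_signatures(cat, rank=2)

    def test_reconstruction_error_non_increasing_in_rank(self, reference):
        rng = np.random.default_rng(4)
        mixes = rng.dirichlet(np.ones(4), size=15)
        cat = simulate_cohort_catalog(mixes, 1000, reference, seed=6)
        errs = [
            extract_signatures(cat, rank=k, seed=1, n_restarts=4).reconstruction_error
            for k in (1, 2, 3)
        ]
        assert errs[0] >= errs[1] >= errs[2]


class TestMatching:
    def test_exact_reference_vector_matches_itself(self, reference):
        sub = SignatureSet(signatures=reference.signatures[1:2], labels=["X"])
        matches = match_to_reference(sub, reference)
        assert matches[0][0] == reference.labels[1]
        assert matches[0][1] == pytest.approx(1.0)

    def test_orthogonal_signature_still_emits_match(self):
        a = np.zeros(96)
        a[0] = 1.0
        b = np.zeros(96)
        b[1] = 1.0
        ref = SignatureSet(signatures=b[None, :], labels=["R"])
        got = match_to_reference(SignatureSet(signatures=a[None, :], labels=["X"]), ref)
        assert got == [("R", 0.0)]

    def test_tie_broken_by_reference_order(self):
        v = np.full(96, 1 / 96)
        ref = SignatureSet(signatures=np.vstack([v, v]), labels=["first", "second"])
        got = match_to_reference(SignatureSet(signatures=v[None, :], labels=["X"]), ref)
        assert got[0][0] == "first"

    def test_channel_order_mismatch_raises(self, reference):
        shuffled = tuple(reversed(CHANNELS))
        sub = SignatureSet(signatures=reference.signatures[:1], labels=["X"], contexts=shuffled)
        with pytest.raises(ChannelOrderError):
            match_to_reference(sub, reference)


class TestContributions:
    def _set(self, expos, samples):
        k = expos.shape[1]
        sigs = np.full((k, 96), 1 / 96)
        return SignatureSet(
            signatures=sigs, labels=[f"S{i}" for i in range(k)],
            exposures=expos, sample_ids=samples,
        )

    def test_relative_normalization(self):
        ss = self._set(np.array([[2.0, 6.0]]), ["a"])
        meta = pd.DataFrame({"grp": ["g"]}, index=["a"])
        out = group_contributions(ss, meta, "grp")
        assert out.loc["g"].tolist() == [0.25, 0.75]

    def test_group_mean_of_relative_contributions(self):
        ss = self._set(np.array([[1.0, 0.0], [0.0, 1.0]]), ["a", "b"])
        meta = pd.DataFrame({"grp": ["g", "g"]}, index=["a", "b"])
        out = group_contributions(ss, meta, "grp")
        assert out.loc["g"].tolist() == [0.5, 0.5]

    def test_zero_exposure_sample_excluded(self):
        ss = self._set(np.array([[1.0, 0.0], [0.0, 0.0]]), ["a", "b"])
        meta = pd.DataFrame({"grp": ["g", "g"]}, index=["a", "b"])
        out = group_contributions(ss, meta, "grp")
        assert out.loc["g"].tolist() == [1.0, 0.0]


class TestSpearman:
    def _set_from_rel(self, rel):
        n = len(rel)
        expos = np.column_stack([rel, 1 - np.asarray(rel)])
        return TestContributions._set(TestContributions(), expos, [f"s{i}" for i in range(n)]), [f"s{i}" for i in range(n)]

    def test_perfect_monotone(self):
        ss, ids = self._set_from_rel(np.linspace(0.1, 0.9, 10))
        rho, _ = correlate_contribution_burden(ss, pd.Series(np.arange(10.0), index=ids), label="S0")
        assert rho == pytest.approx(1.0)

    def test_antitone(self):
        ss, ids = self._set_from_rel(np.linspace(0.1, 0.9, 10))
        rho, _ = correlate_contribution_burden(ss, pd.Series(-np.arange(10.0), index=ids), label="S0")
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_enumeration(self):
        rel = np.array([0.1, 0.4, 0.2, 0.5, 0.3])
        burden = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        ss, ids = self._set_from_rel(rel)
        rho, p = correlate_contribution_burden(ss, pd.Series(burden, index=ids), label="S0")
        # enumerate all 5! rank pairings
        rx = stats.rankdata(rel)
        ry = stats.rankdata(burden)
        rhos = []
        for perm in itertools.permutations(ry):
            rhos.append(stats.pearsonr(rx, np.array(perm))[0])
        exact = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert p == pytest.approx(exact, abs=1e-9)

    def test_constant_input_is_degenerate(self):
        ss, ids = self._set_from_rel(np.full(5, 0.5))
        with pytest.raises(DegenerateInputError):
            correlate_contribution_burden(ss, pd.Series(np.arange(5.0), index=ids), label="S0")
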