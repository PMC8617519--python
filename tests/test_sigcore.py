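"""Spectra, normalization, baseline subtraction, cosine, refitting, INDELs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cinsig.catalog import SignatureCatalog, load_catalog, proxy_catalog
from cinsig.channels import SBS96_LABELS, revcomp
from cinsig.sigcore import (
    TrinucleotideSpectrum,
    build_spectrum,
    classify_indel,
    classify_snv_context,
    cosine_similarity_profile,
    normalize_spectrum,
    pooled_cs_baseline,
    refit_signatures,
    subtract_baseline,
)


def spec(values, **meta):
    v = np.zeros(96)
    v[: len(values)] = values
    return TrinucleotideSpectrum(v, meta=meta or {"scale": "raw"})


class TestClassifySNV:
    def test_pyrimidine_read_off(self):
        ref = {"chr1": "AACTT"}
        idx = classify_snv_context("chr1", 3, "C", "T", ref)
        assert SBS96_LABELS[idx] == "A[C>T]T"

    def test_purine_strand_collapse(self):
        ref = {"chr1": "AAGTT"}
        idx = classify_snv_context("chr1", 3, "G", "A", ref)
        assert SBS96_LABELS[idx] == "A[C>T]T"

    def test_sbs17b_defining_context(self):
        ref = {"chr1": "ACTTG"}
        idx = classify_snv_context("chr1", 3, "T", "G", ref)
        assert SBS96_LABELS[idx] == "C[T>G]T"

    def test_reference_mismatch_names_position(self):
        ref = {"chr1": "AACTT"}
        with pytest.raises(ValueError, match="chr1:3"):
            classify_snv_context("chr1", 3, "G", "A", ref)

    def test_ambiguous_context_rejected(self):
        ref = {"chr1": "ANCTT"}
        with pytest.raises(ValueError, match="ambiguous"):
            classify_snv_context("chr1", 3, "C", "T", ref)


class TestBuildSpectrum:
    def test_counts_and_conservation(self):
        ref = {"chr1": "AACTTAACTTAACTT"}
        variants = pd.DataFrame(
            [("chr1", p, "C", "T") for p in (3, 8, 13)],
            columns=["contig", "pos", "ref", "alt"],
        )
        s = build_spectrum(variants, ref)
        assert s.total == 3
        assert s.values[SBS96_LABELS.index("A[C>T]T")] == 3

    def test_empty_set_zero_vector(self):
        s = build_spectrum(pd.DataFrame(columns=["contig", "pos", "ref", "alt"]), {"chr1": "ACGT"})
        assert s.total == 0

    def test_strand_collapse_invariance(self, tiny_reference):
        # the same physical mutations reported on the purine strand
        seq = tiny_reference["chr1"]
        fwd_rows, rev_rows = [], []
        count = 0
        for pos0 in range(1, len(seq) - 1):
            if seq[pos0] == "C":
                fwd_rows.append(("chr1", pos0 + 1, "C", "T"))
                count += 1
                if count >= 50:
                    break
        rc = {"chr1_rc": revcomp(seq)}
        L = len(seq)
        for _, pos, _, _ in fwd_rows:
            rc_pos = L - pos + 1
            rev_rows.append(("chr1_rc", rc_pos, "G", "A"))
        cols = ["contig", "pos", "ref", "alt"]
        s_fwd = build_spectrum(pd.DataFrame(fwd_rows, columns=cols), tiny_reference)
        s_rev = build_spectrum(pd.DataFrame(rev_rows, columns=cols), rc)
        assert np.array_equal(s_fwd.values, s_rev.values)


class TestNormalize:
    def test_scale_factor(self):
        s = spec([0] * 8 + [8])
        out = normalize_spectrum(s, reads_per_cell=200_000, covered_fraction=0.02)
        assert out.values[8] == pytest.approx(2.0)
        assert out.meta["norm_factor"] == pytest.approx(0.25)

    def test_reference_condition_identity(self):
        s = spec([5, 3])
        out = normalize_spectrum(s, 100_000, 0.01)
        assert np.allclose(out.values, s.values)

    def test_zero_spectrum_stays_zero(self):
        out = normalize_spectrum(spec([]), 50_000, 0.005)
        assert out.total == 0

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError):
            normalize_spectrum(spec([1]), 100_000, 0.0)


class TestSubtractBaseline:
    def test_clipping(self):
        a = spec([5, 3], scale="normalized")
        b = spec([2, 4], scale="normalized")
        out = subtract_baseline(a, b)
        assert out.values[0] == 3 and out.values[1] == 0

    def test_self_subtraction_zero(self):
        a = spec([5, 3, 1], scale="normalized")
        assert subtract_baseline(a, a).total == 0

    def test_zero_baseline_identity(self):
        a = spec([5, 3], scale="normalized")
        z = spec([], scale="normalized")
        assert np.array_equal(subtract_baseline(a, z).values, a.values)

    def test_scale_mismatch_errors(self):
        a = spec([1], scale="normalized")
        b = spec([1], scale="raw")
        with pytest.raises(ValueError, match="scale"):
            subtract_baseline(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=96, max_size=96),
           st.lists(st.floats(0, 100), min_size=96, max_size=96))
    def test_always_non_negative(self, a, b):
        out = subtract_baseline(
            TrinucleotideSpectrum(np.array(a), {"scale": "raw"}),
            TrinucleotideSpectrum(np.array(b), {"scale": "raw"}),
        )
        assert (out.values >= 0).all()


class TestPooledBaseline:
    def test_single_spectrum_identity(self):
        a = spec([2, 4], scale="normalized")
        out = pooled_cs_baseline([a], n_cells=[10])
        assert np.array_equal(out.values, a.values)

    def test_weighted_mean(self):
        a = spec([2, 0], scale="normalized")
        b = spec([0, 2], scale="normalized")
        out = pooled_cs_baseline([a, b], n_cells=[10, 30])
        assert out.values[0] == pytest.approx(0.5)
        assert out.values[1] == pytest.approx(1.5)

    def test_no_spectra_errors(self):
        with pytest.raises(ValueError):
            pooled_cs_baseline([])


class TestCosine:
    def test_match_is_one_and_scale_invariant(self, catalog):
        for scale in (1.0, 7.3, 1e4):
            s = TrinucleotideSpectrum(scale * catalog["SBS17a-proxy"], {"scale": "raw"})
            prof = cosine_similarity_profile(s, catalog)
            assert prof["SBS17a-proxy"] == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        sig = np.zeros(96)
        sig[0] = 1.0
        cat = SignatureCatalog(pd.DataFrame({"point": sig}, index=list(SBS96_LABELS)))
        s = spec([0, 1, 1])
        assert cosine_similarity_profile(s, cat)["point"] == pytest.approx(0.0)

    def test_toy_half(self):
        c = np.zeros(96)
        c[0] = 0.5
        c[2] = 0.5
        cat = SignatureCatalog(pd.DataFrame({"toy": c}, index=list(SBS96_LABELS)))
        s = spec([1, 1, 0])
        assert cosine_similarity_profile(s, cat)["toy"] == pytest.approx(0.5)

    def test_zero_spectrum_errors(self, catalog):
        with pytest.raises(ValueError):
            cosine_similarity_profile(spec([]), catalog)


class TestRefit:
    def test_exact_combination_recovered(self, catalog):
        target = 600 * catalog["SBS17a-proxy"] + 400 * catalog["SBS17b-proxy"]
        s = TrinucleotideSpectrum(target, {"scale": "raw"})
        res = refit_signatures(s, catalog, ["SBS17a-proxy", "SBS17b-proxy"])
        assert res.contributions["SBS17a-proxy"] == pytest.approx(600, abs=1e-6)
        assert res.contributions["SBS17b-proxy"] == pytest.approx(400, abs=1e-6)
        assert res.fraction_explained == pytest.approx(1.0, abs=1e-9)
        assert res.cosine_to_observed == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_zero(self):
        sig = np.zeros(96)
        sig[0] = 1.0
        cat = SignatureCatalog(pd.DataFrame({"point": sig}, index=list(SBS96_LABELS)))
        s = spec([0, 5, 5])
        res = refit_signatures(s, cat, ["point"])
        assert res.contributions["point"] == pytest.approx(0.0)
        assert res.fraction_explained == pytest.approx(0.0)

    def test_zero_spectrum_contract(self, catalog):
        res = refit_signatures(spec([]), catalog, ["SBS17a-proxy"])
        assert res.fraction_explained == 0.0

    def test_noisy_mixture_recovery_with_grid_oracle(self, catalog):
        rng = np.random.default_rng(42)
        A = catalog["SBS17a-proxy"]
        B = catalog["SBS17b-proxy"]
        p = 0.7 * A + 0.3 * B
        counts = rng.multinomial(2000, p * 0.95 + 0.05 / 96)
        s = TrinucleotideSpectrum(counts.astype(float), {"scale": "raw"})
        res = refit_signatures(s, catalog, ["SBS17a-proxy", "SBS17b-proxy"])
        tot = sum(res.contributions.values())
        w_a = res.contributions["SBS17a-proxy"] / tot
        # independent oracle: grid search over the 2-simplex at 0.01 steps
        grid = np.arange(0, 1.0001, 0.01)
        resid = [np.linalg.norm(counts - 2000 * (w * A + (1 - w) * B)) for w in grid]
        w_grid = grid[int(np.argmin(resid))]
        assert abs(w_a - 0.7) <= 0.05
        assert abs(w_a - w_grid) <= 0.05


class TestClassifyIndel:
    def test_t_insertion_in_polyt_run(self):
        ref = {"chr1": "ACTTTTGA"}
        # insert T after the C (run of 4 Ts 3' of the insertion point)
        assert classify_indel("chr1", 2, "C", "CT", ref) == "1bp_ins_T_hp4"
        # same event anchored at the last T of the run
        assert classify_indel("chr1", 6, "T", "TT", ref) == "1bp_ins_T_hp4"

    def test_single_c_deletion(self):
        ref = {"chr1": "TACGT"}
        assert classify_indel("chr1", 2, "AC", "A", ref) == "1bp_del_C_hp1"

    def test_purine_collapse(self):
        ref = {"chr1": "TCAAAG"}
        # deleting one A from a 3-run counts as a T deletion on the other strand
        assert classify_indel("chr1", 2, "CA", "C", ref) == "1bp_del_T_hp3"

    def test_dinucleotide_insertion_at_repeat(self):
        ref = {"chr1": "GATATATC"}
        # insert AT right after ...ATATAT (3 preceding copies)
        assert classify_indel("chr1", 7, "T", "TAT", ref) == "ins_rep_3+"

    def test_multibp_insertion_without_repeat(self):
        ref = {"chr1": "GGCCGG"}
        assert classify_indel("chr1", 3, "C", "CTA", ref) == "other_ins"

    def test_multibp_deletion_other(self):
        ref = {"chr1": "GATCGA"}
        assert classify_indel("chr1", 2, "ATC", "A", ref) == "other_del"

    def test_reference_mismatch(self):
        ref = {"chr1": "TACGT"}
        with pytest.raises(ValueError, match="chr1:2"):
            classify_indel("chr1", 2, "AG", "A", ref)


class TestCatalog:
    def test_proxy_constructions(self, catalog):
        a = catalog["SBS17a-proxy"]
        assert a[SBS96_LABELS.index("C[T>C]T")] == pytest.approx(0.90)
        off = np.delete(a, SBS96_LABELS.index("C[T>C]T"))
        assert np.allclose(off, 0.10 / 95)
        b = catalog["SBS17b-proxy"]
        for f in "ACGT":
            assert b[SBS96_LABELS.index(f"{f}[T>G]T")] == pytest.approx(0.225)
        assert np.allclose(sum(catalog[n].sum() for n in catalog.names), len(catalog.names))

    def test_load_cosmic_layout_roundtrip(self, tmp_path, catalog):
        path = tmp_path / "cat.tsv"
        df = catalog.df.reset_index().rename(columns={"index": "Type"})
        df.to_csv(path, sep="\t", index=False)
        back = load_catalog(path)
        assert np.allclose(back.df.to_numpy(), catalog.df.to_numpy())

    def test_malformed_row_count(self, tmp_path, catalog):
        path = tmp_path / "bad.tsv"
        df = catalog.df.reset_index().rename(columns={"index": "Type"}).iloc[:95]
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="96"):
            load_catalog(path)

    def test_negative_entries_rejected(self):
        bad = np.full(96, 1 / 96)
        bad[0] = -0.1
        with pytest.raises(ValueError, match="negative"):
            SignatureCatalog(pd.DataFrame({"bad": bad}, index=list(SBS96_LABELS)))
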