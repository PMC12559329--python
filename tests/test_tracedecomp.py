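"""Chromatogram simulation, template building and NNLS decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nickloop import (
    build_simulated_reference,
    build_templates,
    decompose,
    simulate_trace,
    summarize_indels,
)
from nickloop.errors import ConfigError
from nickloop.pipeline import (
    contraction_readout,
    decompose_mixture,
    expansion_readout,
    make_standard_substrate,
)
from nickloop.substrates import revcomp
from nickloop.tracedecomp import (
    CHANNELS,
    noiseless_channels,
    read_chromatogram_tsv,
    write_chromatogram_tsv,
)


@pytest.fixture(scope="module")
def expansion_setup(standard_substrate):
    control, product, site = expansion_readout(standard_substrate)
    templates = build_templates(control, site, (-15, 15), expected_insert_bases="CTG")
    return control, product, site, templates


class TestSimulateTrace:
    def test_single_sequence_noiseless_one_channel_per_scan(self):
        seq = "ACGTTGCA"
        chrom = simulate_trace([(seq, 1.0)])
        assert chrom.called_sequence == seq
        for t, base in enumerate(seq):
            nz = np.nonzero(chrom.scans[t])[0]
            assert list(nz) == [CHANNELS.index(base)]

    def test_mixture_splits_channels_where_sequences_differ(self):
        a = "ACGT" * 10
        b = a[:8] + "TTTT" + a[8:]  # +4 insertion at scan 8
        chrom = simulate_trace([(a, 0.5), (b, 0.5)], decay_rate=0.0)
        for t in range(8):  # shared prefix: single full-height channel
            assert chrom.scans[t].max() == pytest.approx(1.0)
        diff = [t for t in range(12, 40) if a[t] != b[t]]
        for t in diff[:5]:
            vals = sorted(chrom.scans[t])[::-1]
            assert vals[0] == pytest.approx(0.5) and vals[1] == pytest.approx(0.5)

    def test_fixed_seed_reproducible(self):
        kw = dict(noise_sd=0.05, seed=3)
        c1 = simulate_trace([("ACGT" * 20, 1.0)], **kw)
        c2 = simulate_trace([("ACGT" * 20, 1.0)], **kw)
        assert np.array_equal(c1.scans, c2.scans)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            simulate_trace([("ACGT", 0.6), ("ACGT", 0.6)])

    def test_tsv_round_trip(self, tmp_path):
        chrom = simulate_trace([("ACGTTACG" * 8, 1.0)], noise_sd=0.02, seed=1)
        path = tmp_path / "trace.tsv"
        write_chromatogram_tsv(chrom, path)
        back = read_chromatogram_tsv(path)
        assert back.called_sequence == chrom.called_sequence
        assert np.allclose(back.scans, chrom.scans, atol=1e-5)


class TestSimulatedReference:
    def test_insertion_and_deletion(self, standard_substrate):
        control, _, site = expansion_readout(standard_substrate)
        ins_seq, ins_trace = build_simulated_reference(control, 12, site, "CTG" * 4)
        assert len(ins_seq) == len(control) + 12
        assert ins_seq[site:site + 12] == "CTG" * 4
        ctrl_loop, _, csite = contraction_readout(standard_substrate)
        del_seq, _ = build_simulated_reference(ctrl_loop, -12, csite)
        # deleting the loop reproduces the contraction-product strand read-out
        _, product, _ = contraction_readout(standard_substrate)
        assert del_seq == product

    def test_zero_shift_identity(self):
        seq, trace = build_simulated_reference("ACGT" * 30, 0, 10)
        assert seq == "ACGT" * 30
        assert trace.called_sequence == seq

    def test_deletion_past_end_rejected(self):
        with pytest.raises(ConfigError):
            build_simulated_reference("ACGTACGT", -6, 5)


class TestTemplates:
    def test_shift_family_shape(self, expansion_setup):
        control, _, site, templates = expansion_setup
        assert templates.n_templates == 31
        for s in templates.shifts:
            assert templates.matrices[s].shape == (80, 4)

    def test_zero_shift_equals_control_trace(self, expansion_setup):
        control, _, site, templates = expansion_setup
        w0, w1 = templates.window
        assert np.allclose(templates.matrices[0],
                           noiseless_channels(control)[w0:w1])

    def test_plus12_template_equals_expansion_product_trace(self, expansion_setup):
        """The +12 simulated reference reproduces the true expansion product's
        noiseless chromatogram over the window."""
        control, product, site, templates = expansion_setup
        w0, w1 = templates.window
        product_trace = simulate_trace([(product, 1.0)])
        assert np.allclose(templates.matrices[12], product_trace.scans[w0:w1])
        assert templates.inserted_bases(12) == "CTG" * 4

    def test_window_outside_bounds_rejected(self):
        with pytest.raises(ConfigError):
            build_templates("ACGT" * 30, 20, (-15, 15), window=(40, 200))


class TestDecompose:
    def test_pure_control_recovered(self, expansion_setup):
        control, _, _, templates = expansion_setup
        res = decompose(simulate_trace([(control, 1.0)]), templates)
        assert res.fraction(0) == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)
        assert summarize_indels(res)["call"] == "no significant indel"

    def test_noiseless_50_50_exact(self, expansion_setup):
        control, _, _, templates = expansion_setup
        mix = simulate_trace([(control, 0.5), (templates.sequences[12], 0.5)])
        res = decompose(mix, templates)
        assert res.fraction(0) == pytest.approx(0.5, abs=1e-9)
        assert res.fraction(12) == pytest.approx(0.5, abs=1e-9)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(-15, 15), st.floats(0.05, 1.0)),
                    min_size=1, max_size=5, unique_by=lambda t: t[0]))
    def test_noiseless_mixture_exactness(self, expansion_setup, components):
        """Any noiseless mixture of templates is recovered to machine precision."""
        _, _, _, templates = expansion_setup
        total = sum(w for _, w in components)
        mixture = [(templates.sequences[s], w / total) for s, w in components]
        res = decompose(simulate_trace(mixture), templates)
        for s, w in components:
            assert res.fraction(s) == pytest.approx(w / total, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_recovery_unbiased_at_planted_fractions(self, expansion_setup):
        control, _, _, templates = expansion_setup
        for planted in (0.155, 0.5):
            vals = []
            for seed in range(40, 60):
                mix = simulate_trace([(control, 1 - planted),
                                      (templates.sequences[12], planted)],
                                     noise_sd=0.02, seed=seed)
                vals.append(decompose(mix, templates).fraction(12))
            assert abs(np.mean(vals) - planted) <= 0.01

    def test_r_squared_decreases_with_noise(self, expansion_setup):
        control, _, _, templates = expansion_setup
        means = []
        for noise in (0.005, 0.02, 0.05):
            r2 = [decompose(simulate_trace([(control, 1.0)], noise_sd=noise, seed=s),
                            templates).r_squared for s in range(50)]
            means.append(np.mean(r2))
        assert means[0] > means[1] > means[2]

    def test_null_per_shift_error_rate_within_alpha(self, expansion_setup):
        """Under the null, spurious significant shifts occur at most at the
        nominal per-component rate."""
        control, _, _, templates = expansion_setup
        hits = sum(len(decompose(simulate_trace([(control, 1.0)], noise_sd=0.01,
                                                seed=5000 + s),
                                 templates).significant_shifts)
                   for s in range(200))
        from scipy import stats
        assert hits <= stats.binom.ppf(0.999, 200 * 30, 0.001)

    def test_bonferroni_controls_familywise_null_rate(self, expansion_setup):
        """With the Bonferroni option, runs reporting any spurious indel stay
        at the alpha level."""
        control, _, _, templates = expansion_setup
        runs = sum(bool(decompose(simulate_trace([(control, 1.0)], noise_sd=0.01,
                                                 seed=7000 + s),
                                  templates, bonferroni=True).significant_shifts)
                   for s in range(200))
        from scipy import stats
        assert runs <= stats.binom.ppf(0.999, 200, 0.001)

    def test_mutant_shorter_than_window_rejected(self, expansion_setup):
        control, _, _, templates = expansion_setup
        short = simulate_trace([(control[:templates.window[1] - 10], 1.0)])
        with pytest.raises(ConfigError):
            decompose(short, templates)

    def test_periodic_context_handled(self):
        """A fully repeat-periodic context makes shift templates collinear;
        decompose must either flag the degeneracy or still fit exactly."""
        from nickloop.errors import DegenerateTemplatesError
        control = "CAG" * 60
        templates = build_templates(control, 60, (-6, 6), expected_insert_bases="CAG",
                                    window=(70, 120))
        mix = simulate_trace([(control, 0.7), (templates.sequences[3], 0.3)])
        try:
            res = decompose(mix, templates)
        except DegenerateTemplatesError:
            return
        assert res.r_squared == pytest.approx(1.0)


class TestSummaries:
    def test_expansion_summary(self, standard_substrate):
        res, summary, _, _ = decompose_mixture(standard_substrate, "expansion",
                                               0.5, 0.01, seed=3)
        assert summary["dominant_shift"] == 12
        assert summary["dominant_insert"] == revcomp(standard_substrate.loop.loop_sequence)
        assert summary["insert_matches_loop_complement"]
        assert "expansion" in summary["call"]
        assert 0 < summary["insertion_signal_incl_residual"] <= summary["insertion_signal"]

    def test_contraction_summary(self, standard_substrate):
        res, summary, _, _ = decompose_mixture(standard_substrate, "contraction",
                                               0.75, 0.01, seed=4)
        assert summary["dominant_shift"] == -12
        assert summary["shortening_signal"] == pytest.approx(0.75, abs=0.05)
        assert "contraction" in summary["call"]
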