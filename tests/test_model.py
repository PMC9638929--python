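"""Counts -> translational states -> peak assignment -> rendered profile."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyprofile import (
    CellParams,
    DegenerateInputError,
    FixtureSpec,
    InvalidInputError,
    PeakVolumes,
    add_inactive,
    align,
    assign_to_peaks,
    compute_states,
    fit_profile,
    make_count_table,
    model_counts,
    peak_volumes,
    predict_positions,
    render_modelled_profile,
    truth_volumes,
)

YEAST = CellParams.preset("yeast")


def table(gene_ids, lengths, fp, rna):
    return pd.DataFrame({"gene_id": gene_ids, "length_nt": lengths,
                         "fp_count": fp, "rna_count": rna})


class TestCellParams:
    def test_presets(self):
        assert YEAST.total_mrna == 60_000
        assert YEAST.total_ribosomes == 200_000
        assert YEAST.active_fraction == 0.85
        assert YEAST.split_fraction == 0.3
        assert YEAST.small_subunit_fraction == 0.35
        hek = CellParams.preset("hek293")
        assert hek.total_mrna == 300_000
        assert hek.total_ribosomes == 2_000_000
        assert hek.small_subunit_fraction == 0.37

    def test_overrides_and_validation(self):
        tweaked = CellParams.preset("yeast", split_fraction=0.5)
        assert tweaked.split_fraction == 0.5
        with pytest.raises(InvalidInputError):
            CellParams(active_fraction=1.2)
        with pytest.raises(InvalidInputError):
            CellParams.preset("e_coli")


class TestComputeStates:
    def test_two_gene_symmetry(self):
        counts = table(["a", "b"], [900, 900], [1, 1], [1, 1])
        params = CellParams(total_mrna=100, total_ribosomes=200,
                            active_fraction=1.0)
        states, _ = compute_states(counts, params)
        assert np.allclose(states["rna_copies"], [50, 50])
        assert np.allclose(states["ribosomes_bound"], [100, 100])
        assert np.allclose(states["density"], [2.0, 2.0])

    def test_single_gene_gets_everything(self):
        counts = table(["a"], [1200], [7], [3])
        states, _ = compute_states(counts, YEAST)
        assert states["rna_copies"].iloc[0] == pytest.approx(YEAST.total_mrna)
        assert states["ribosomes_bound"].iloc[0] == pytest.approx(
            YEAST.total_ribosomes * YEAST.active_fraction)

    def test_simulated_densities_recovered_within_2pct(self):
        spec = FixtureSpec(seed=21, n_genes=50, depth_fp=20_000_000,
                           depth_rna=20_000_000)
        counts, truth, params = make_count_table(spec)
        states, _ = compute_states(counts, params)
        merged = states.merge(truth, on="gene_id", suffixes=("", "_true"))
        rel = np.abs(merged["density"] - merged["density_true"]) / merged["density_true"]
        assert rel.max() < 0.02

    def test_zero_rna_genes_excluded_and_reported(self):
        counts = table(["a", "b", "c"], [900, 900, 900], [5, 5, 5], [2, 0, 2])
        states, qc = compute_states(counts, YEAST)
        assert list(states["gene_id"]) == ["a", "c"]
        assert qc["excluded_zero_rna"] == ["b"]
        assert qc["excluded_footprint_counts"] == 5

    def test_degenerate_tables(self):
        with pytest.raises(DegenerateInputError):
            compute_states(table(["a"], [900], [1], [0]), YEAST)
        with pytest.raises(DegenerateInputError):
            compute_states(table(["a"], [900], [0], [1]), YEAST)

    def test_over_cap_fraction_reported(self):
        # 300 nt gene can hold at most 10 ribosomes; give it density 20
        counts = table(["hot", "cold"], [300, 3000], [97, 3], [1, 99])
        params = CellParams(total_mrna=100, total_ribosomes=100,
                            active_fraction=1.0)
        states, qc = compute_states(counts, params)
        hot = states.set_index("gene_id").loc["hot"]
        assert hot["density"] > 300 / 30  # not truncated
        assert qc["over_cap_fraction"] == pytest.approx(0.5)


class TestAssignToPeaks:
    def test_worked_example_density_5_8(self):
        states = pd.DataFrame({"gene_id": ["g"], "rna_copies": [10.0],
                               "ribosomes_bound": [58.0], "density": [5.8]})
        masses, _ = assign_to_peaks(states)
        assert masses[5] == pytest.approx(11.6, abs=1e-12)
        assert masses[6] == pytest.approx(46.4, abs=1e-12)

    def test_integer_density_single_peak(self):
        states = pd.DataFrame({"gene_id": ["g"], "rna_copies": [10.0],
                               "ribosomes_bound": [30.0], "density": [3.0]})
        masses, _ = assign_to_peaks(states)
        assert masses == {3: 30.0}

    def test_sub_monosomal_density_contributes_to_peak_zero(self):
        states = pd.DataFrame({"gene_id": ["g"], "rna_copies": [10.0],
                               "ribosomes_bound": [4.0], "density": [0.4]})
        masses, info = assign_to_peaks(states)
        assert masses[0] == pytest.approx(2.4)
        assert masses[1] == pytest.approx(1.6)
        assert info["peak0_mass"] == pytest.approx(2.4)

    def test_mass_pooled_above_n_max(self):
        states = pd.DataFrame({"gene_id": ["g"], "rna_copies": [1.0],
                               "ribosomes_bound": [25.0], "density": [25.0]})
        masses, info = assign_to_peaks(states, n_max=20)
        assert masses[20] == pytest.approx(25.0)
        assert info["pooled_mass"] == pytest.approx(25.0)

    def test_negative_density_rejected(self):
        states = pd.DataFrame({"gene_id": ["g"], "rna_copies": [1.0],
                               "ribosomes_bound": [1.0], "density": [-0.1]})
        with pytest.raises(InvalidInputError):
            assign_to_peaks(states)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_ribosome_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        states = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "rna_copies": rng.uniform(0.1, 100, n),
            "ribosomes_bound": rng.uniform(0, 500, n),
            "density": rng.uniform(0, 30, n),
        })
        masses, _ = assign_to_peaks(states, n_max=20)
        total = sum(masses.values())
        expected = states["ribosomes_bound"].sum()
        assert abs(total - expected) / expected < 1e-9

    def test_density_shift_moves_mass_one_peak_up(self):
        base = pd.DataFrame({"gene_id": ["g"], "rna_copies": [10.0],
                             "ribosomes_bound": [58.0], "density": [5.8]})
        shifted = base.assign(density=[6.8])
        m0, _ = assign_to_peaks(base)
        m1, _ = assign_to_peaks(shifted)
        assert m1 == {k + 1: v for k, v in m0.items()}


class TestAddInactive:
    def test_idle_only_profile_fractions(self):
        volumes = add_inactive({}, YEAST, include_idle=True)
        # inactive pool 30 000: 40S 0.105, 60S 0.195, monosome 0.700
        assert volumes[0.35] == pytest.approx(0.105)
        assert volumes[0.65] == pytest.approx(0.195)
        assert volumes[1.0] == pytest.approx(0.700)

    def test_include_idle_off_is_pass_through(self):
        masses = {0: 50.0, 1: 10.0, 2: 30.0, 3: 60.0}
        volumes = add_inactive(masses, YEAST, include_idle=False)
        assert 0.35 not in volumes and 0.65 not in volumes
        assert volumes[1.0] == pytest.approx(0.1)
        assert volumes[2.0] == pytest.approx(0.3)
        assert volumes[3.0] == pytest.approx(0.6)

    def test_idle_share_matches_brute_force(self, yeast_counts):
        counts, _, params = yeast_counts
        states, _ = compute_states(counts, params)
        masses, _ = assign_to_peaks(states)
        volumes = add_inactive(masses, params, include_idle=True)
        # independent recomputation of the subunit + idle-monosome share
        nsome = sum(v for k, v in masses.items() if k >= 1)
        inactive = params.total_ribosomes * (1 - params.active_fraction)
        idle_share = inactive / (inactive + nsome)
        got = (volumes[0.35] + volumes[0.65]
               + inactive * (1 - params.split_fraction) / (inactive + nsome))
        assert got == pytest.approx(idle_share)
        assert volumes.is_normalized(1e-9)


class TestPipelineInvariances:
    def test_doubling_counts_changes_nothing(self, yeast_counts):
        counts, _, params = yeast_counts
        doubled = counts.assign(fp_count=counts["fp_count"] * 2,
                                rna_count=counts["rna_count"] * 2)
        v1, _ = model_counts(counts, params)
        v2, _ = model_counts(doubled, params)
        _, m = align([v1, v2])
        assert np.allclose(m[0], m[1], atol=1e-12)

    def test_truth_vector_recovered_within_sampling_error(self, yeast_spec, yeast_counts):
        counts, truth, params = yeast_counts
        prescribed = truth_volumes(truth, yeast_spec)
        recovered, _ = model_counts(counts, params, include_idle=False)
        _, m = align([prescribed, recovered])
        # depth 1e6 on 600 genes: generous sampling-error budget
        assert np.max(np.abs(m[0] - m[1])) < 0.01


class TestRender:
    def test_unit_area(self, yeast_spec):
        volumes = PeakVolumes({1.0: 1.0})
        trace = render_modelled_profile(volumes, yeast_spec.location_model)
        area = np.trapezoid(trace.absorbance, trace.position)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_equal_volumes_equal_maxima(self):
        from polyprofile import PeakLocationModel
        model = PeakLocationModel(a=30.0, b=10.0)
        volumes = PeakVolumes({1.0: 0.5, 2.0: 0.5})
        trace = render_modelled_profile(volumes, model, width_factor=0.1,
                                        n_points=8001)
        y = trace.absorbance
        mid = y.size // 2
        assert abs(y[:mid].max() - y[mid:].max()) / y.max() < 1e-3

    def test_render_then_refit_recovers_volumes(self, yeast_spec, yeast_counts):
        counts, _, params = yeast_counts
        volumes, _ = model_counts(counts, params)
        location = yeast_spec.location_model
        trace = render_modelled_profile(volumes, location)
        mus = predict_positions(location, volumes.indices)
        fitted = fit_profile(trace, dict(zip(volumes.indices, mus)))
        refit = peak_volumes(fitted)
        _, m = align([volumes, refit])
        assert np.max(np.abs(m[0] - m[1])) < 1e-3

    def test_unnormalized_volumes_rejected(self, yeast_spec):
        with pytest.raises(InvalidInputError):
            render_modelled_profile(PeakVolumes({1.0: 0.5}),
                                    yeast_spec.location_model)
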