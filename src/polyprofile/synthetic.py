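"""Ground-truth fixture generation.

Everything the rest of the package consumes — count tables, gradient traces,
known-good volume collections — can be synthesized here with the generating
truth returned alongside, so the full pipeline is testable end to end
without any external datasets.

The default parameters sketch a fast-growing yeast cell: ~60 000 mRNA
copies, 85% of ribosomes translating, gene-level ribosome densities
log-normal with median 2 ribosomes/transcript (yielding profiles peaking
around the tri-some), CDS lengths log-normal around 1.2 kb, and densities
capped at the physical packing limit of one ribosome per 10 codons.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fitting import DebrisBaseline, GaussianPeak, ProfileModel, evaluate_model, local_spacings
from .model import CellParams, assign_to_peaks
from .peaks import PeakLocationModel, ProfileTrace, predict_positions
from .volumes import PeakVolumes


@dataclass(frozen=True)
class FixtureSpec:
    """Parametric description of a synthetic experiment.

    The same seed always reproduces the same fixture; no file state.
    """

    seed: int = 0
    n_genes: int = 2000
    # cell constants
    total_mrna: float = 60_000.0
    active_fraction: float = 0.85
    split_fraction: float = 0.3
    small_subunit_fraction: float = 0.35
    # per-gene ribosome density, log-normal, truncated at length_nt/30
    density_logmean: float = math.log(2.0)
    density_logsd: float = 0.6
    # per-gene mRNA copy number, log-normal (relative; rescaled to total_mrna)
    expression_logmean: float = math.log(5.0)
    expression_logsd: float = 1.0
    # CDS length in nt, log-normal, floored at 300 nt
    length_logmean: float = math.log(1200.0)
    length_logsd: float = 0.45
    # sequencing depths (total simulated reads, multinomial)
    depth_fp: int = 5_000_000
    depth_rna: int = 5_000_000
    # trace rendering
    trace_noise_sd: float = 0.01      # fraction of max signal
    location_a: float = 15.0
    location_b: float = 30.0
    width_factor: float = 0.2
    n_max: int = 20
    # background, in the same arbitrary OD units as the unit-area peak set:
    # the debris peak rises to a few times the monosome peak height, as in
    # real traces, and the baseline drifts gently upward
    trace_points: int = 1200
    debris_amplitude: float = 0.15
    debris_decay: float = 0.3
    baseline_slope: float = 2e-4
    baseline_offset: float = 0.01

    def __post_init__(self):
        if self.n_genes < 1 or self.depth_fp < 1 or self.depth_rna < 1:
            raise InvalidInputError("n_genes and depths must be positive")
        for name in ("total_mrna", "width_factor", "location_a"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        for name in ("density_logsd", "expression_logsd", "length_logsd",
                     "trace_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    @property
    def location_model(self) -> PeakLocationModel:
        return PeakLocationModel(a=self.location_a, b=self.location_b)


def make_count_table(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, CellParams]:
    """Simulate a per-gene count table with known translational truth.

    Draws gene lengths, mRNA copies and ribosome densities from the spec's
    distributions; copies are rescaled to sum to ``total_mrna`` and the cell
    parameters returned set ``total_ribosomes`` so that the generated bound
    ribosomes make up exactly the active pool — the downstream normalisation
    then recovers the generating densities in expectation.  Expected
    footprint reads per gene are proportional to bound ribosomes
    (copies × density); expected RNA reads to copies × length (the inverse
    of the RPK transform).  Realized counts are multinomial at the requested
    depths, so totals are exact.

    Returns ``(counts, truth, params)`` with ``truth`` holding the
    generating gene states (gene_id, length_nt, rna_copies, ribosomes_bound,
    density).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = np.maximum(
        np.round(rng.lognormal(spec.length_logmean, spec.length_logsd, spec.n_genes)),
        300.0)
    copies = rng.lognormal(spec.expression_logmean, spec.expression_logsd, spec.n_genes)
    copies *= spec.total_mrna / copies.sum()
    densities = rng.lognormal(spec.density_logmean, spec.density_logsd, spec.n_genes)
    densities = np.minimum(densities, lengths / 30.0)  # packing cap

    ribosomes = copies * densities
    params = CellParams(
        total_mrna=spec.total_mrna,
        total_ribosomes=ribosomes.sum() / spec.active_fraction,
        active_fraction=spec.active_fraction,
        split_fraction=spec.split_fraction,
        small_subunit_fraction=spec.small_subunit_fraction,
    )

    p_fp = ribosomes / ribosomes.sum()
    p_rna = copies * lengths
    p_rna = p_rna / p_rna.sum()
    fp_counts = rng.multinomial(spec.depth_fp, p_fp)
    rna_counts = rng.multinomial(spec.depth_rna, p_rna)

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    counts = pd.DataFrame({
        "gene_id": gene_ids,
        "length_nt": lengths.astype(int),
        "fp_count": fp_counts,
        "rna_count": rna_counts,
    })
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "length_nt": lengths.astype(int),
        "rna_copies": copies,
        "ribosomes_bound": ribosomes,
        "density": densities,
    })
    return counts, truth, params


def truth_volumes(truth: pd.DataFrame, spec: FixtureSpec) -> PeakVolumes:
    """The n-some volume vector implied by the generating gene states."""
    masses, _ = assign_to_peaks(truth, n_max=spec.n_max)
    return PeakVolumes({float(k): v for k, v in masses.items() if k >= 1}).normalized()


def make_trace(
    spec: FixtureSpec,
    volumes: PeakVolumes,
) -> tuple[ProfileTrace, ProfileModel]:
    """Render a volume vector as a noisy gradient trace with known truth.

    Peaks sit at the spec's logarithmic location model with
    sigma = width_factor × local spacing, on top of the spec's debris decay
    and linear baseline; Gaussian noise is added at ``trace_noise_sd`` times
    the maximum signal.  Returns the trace and the exact generating model.
    """
    location = spec.location_model
    indices = volumes.indices
    mus = predict_positions(location, indices)
    if mus.size >= 2:
        sigmas = spec.width_factor * local_spacings(mus)
    else:
        sigmas = np.array([spec.width_factor * spec.location_a * math.log(2.0)])
    peaks = [GaussianPeak(index=i, mu=float(m), sigma=float(sg), s=float(v))
             for i, m, sg, v in zip(indices, mus, sigmas, volumes.values_array)]
    background = DebrisBaseline(amplitude=spec.debris_amplitude,
                                decay=spec.debris_decay,
                                slope=spec.baseline_slope,
                                offset=spec.baseline_offset)
    model = ProfileModel(peaks=peaks, background=background)

    x0 = min(0.0, mus[0] - 4 * sigmas[0])
    grid = np.linspace(x0, mus[-1] + 4 * sigmas[-1], spec.trace_points)
    clean = evaluate_model(model, grid)
    rng = np.random.default_rng(spec.seed + 1)
    noise = (rng.normal(0.0, spec.trace_noise_sd * clean.max(), grid.size)
             if spec.trace_noise_sd > 0 else 0.0)
    return ProfileTrace(position=grid, absorbance=clean + noise), model


def make_known_good_collection(
    spec: FixtureSpec,
    n_datasets: int,
    base: PeakVolumes | None = None,
    perturbation_sd: float = 0.05,
) -> list[PeakVolumes]:
    """Perturbed replicates of one base vector, for fitting the RMSD null.

    Each replicate multiplies every peak volume by exp(N(0, perturbation_sd))
    and renormalizes — small, dataset-like wobble around a common profile.
    """
    if n_datasets < 3:
        raise InvalidInputError(f"need >= 3 datasets, got {n_datasets}")
    if base is None:
        _, truth, _ = make_count_table(spec)
        base = truth_volumes(truth, spec)
    rng = np.random.default_rng(spec.seed + 2)
    out = []
    for _ in range(n_datasets):
        factors = (np.exp(rng.normal(0.0, perturbation_sd, len(base)))
                   if perturbation_sd > 0 else np.ones(len(base)))
        out.append(PeakVolumes(dict(zip(base.indices,
                                        base.values_array * factors))).normalized())
    return out


_DEFAULT_KNOWN_GOOD_SPEC = FixtureSpec(seed=20220818, n_genes=1500,
                                       depth_fp=2_000_000, depth_rna=2_000_000)


def default_known_good(n_datasets: int = 31) -> list[PeakVolumes]:
    """The packaged known-good collection (deterministic, built on demand).

    A fixed-seed synthetic stand-in for a curated collection of well-behaved
    yeast datasets; lets RMSD P-values be computed offline out of the box.
    Identical on every call.
    """
    return make_known_good_collection(_DEFAULT_KNOWN_GOOD_SPEC, n_datasets)
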