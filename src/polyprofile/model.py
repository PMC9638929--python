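"""From footprint and RNA-Seq counts to a modelled polysome profile.

The information in a ribosome-footprinting experiment can be projected down
to the information level of a polysome profile.  Per gene, RNA-Seq counts
converted to reads-per-kilobase (RPK) give relative transcript abundances,
which scaled to the cell's total mRNA complement give copies per cell;
footprint counts scaled to the active ribosome pool give bound ribosomes per
cell; their ratio is the mean ribosome density per transcript copy.  A gene
of density d contributes its ribosome mass to the two integer n-some peaks
straddling d, split linearly by the fractional part.  The free (inactive)
ribosome pool, invisible to footprinting, is restored from organism-level
constants: a fraction of inactive ribosomes dissociates into 40S/60S
subunits, the rest sits on the monosome peak.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError, InvalidInputError
from .fitting import _gauss, local_spacings
from .peaks import PeakLocationModel, ProfileTrace, predict_positions, subunit_indices
from .volumes import PeakVolumes

log = logging.getLogger(__name__)

#: nucleotides of coding sequence per ribosome at maximal packing
#: (one ribosome every 10 codons)
_NT_PER_RIBOSOME_CAP = 30.0

REQUIRED_COLUMNS = ("gene_id", "length_nt", "fp_count", "rna_count")


@dataclass(frozen=True)
class CellParams:
    """Organism-level constants completing the modelled profile.

    total_mrna
        mRNA copies per cell.
    total_ribosomes
        Ribosomes per cell.
    active_fraction
        Fraction of ribosomes engaged in translation.
    split_fraction
        Fraction of the *inactive* ribosomes dissociated into free subunits;
        the remainder sit as idle 80S monosomes.
    small_subunit_fraction
        Small-subunit mass fraction of a full ribosome; sets the fractional
        gradient indices of the 40S (fraction) and 60S (1 - fraction) peaks.
    """

    total_mrna: float = 60_000.0
    total_ribosomes: float = 200_000.0
    active_fraction: float = 0.85
    split_fraction: float = 0.3
    small_subunit_fraction: float = 0.35

    def __post_init__(self):
        if self.total_mrna <= 0 or self.total_ribosomes <= 0:
            raise InvalidInputError("totals must be > 0")
        for name in ("active_fraction", "split_fraction", "small_subunit_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def preset(cls, name: str, **overrides) -> "CellParams":
        try:
            params = PRESETS[name.lower()]
        except KeyError:
            raise InvalidInputError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
        try:
            return replace(params, **overrides) if overrides else params
        except TypeError as exc:
            raise InvalidInputError(f"unknown parameter override: {exc}") from None


# Yeast constants are literature estimates for fast growth in rich medium.
# The mammalian split fraction reflects the visibly larger free-subunit peaks
# of HEK293 gradients and should be treated as tunable; the active fraction
# for HEK293 is not well determined and ships at the yeast value.
PRESETS = {
    "yeast": CellParams(total_mrna=60_000, total_ribosomes=200_000,
                        active_fraction=0.85, split_fraction=0.3,
                        small_subunit_fraction=0.35),
    "hek293": CellParams(total_mrna=300_000, total_ribosomes=2_000_000,
                         active_fraction=0.85, split_fraction=0.6,
                         small_subunit_fraction=0.37),
}


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a per-gene count table and coerce dtypes."""
    missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise InvalidInputError(f"count table missing columns: {missing}")
    counts = counts.loc[:, list(REQUIRED_COLUMNS)].copy()
    if counts["gene_id"].duplicated().any():
        dups = counts.loc[counts["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise InvalidInputError(f"duplicate gene_ids: {dups}")
    for col in ("length_nt", "fp_count", "rna_count"):
        counts[col] = pd.to_numeric(counts[col])
        if (counts[col] < 0).any():
            raise InvalidInputError(f"negative values in column {col}")
    if (counts["length_nt"] <= 0).any():
        raise InvalidInputError("gene lengths must be > 0")
    return counts


def compute_states(counts: pd.DataFrame, params: CellParams) -> tuple[pd.DataFrame, dict]:
    """Per-gene translational state from counts and cell constants.

    Returns ``(states, qc)`` where ``states`` has columns gene_id,
    rna_copies, ribosomes_bound, density and ``qc`` reports excluded genes
    (fp_count > 0 but rna_count == 0, which would imply infinite density)
    and the fraction of genes whose density exceeds the physical packing cap
    of one ribosome per 10 codons.  Densities above the cap are *not*
    truncated — an implausible load is a data-quality signal, not a
    modelling artefact to hide.
    """
    counts = validate_counts(counts)
    if counts["rna_count"].sum() == 0 or counts["fp_count"].sum() == 0:
        raise DegenerateInputError("count table has zero total RNA or footprint counts")

    zero_rna = counts["rna_count"] == 0
    excluded = counts.loc[zero_rna & (counts["fp_count"] > 0), "gene_id"].tolist()
    kept = counts.loc[~zero_rna].reset_index(drop=True)

    rpk = kept["rna_count"] / (kept["length_nt"] / 1000.0)
    rna_copies = rpk / rpk.sum() * params.total_mrna
    # normalise over the kept genes so the active ribosome pool is conserved
    # exactly across the assigned peaks
    fp_total = kept["fp_count"].sum()
    if fp_total == 0:
        raise DegenerateInputError("no footprint counts on genes with RNA signal")
    ribosomes = (kept["fp_count"] / fp_total
                 * params.total_ribosomes * params.active_fraction)
    density = ribosomes / rna_copies

    states = pd.DataFrame({
        "gene_id": kept["gene_id"],
        "rna_copies": rna_copies,
        "ribosomes_bound": ribosomes,
        "density": density,
    })
    cap = kept["length_nt"] / _NT_PER_RIBOSOME_CAP
    over_cap = float((density > cap).mean())
    qc = {
        "n_genes": int(len(counts)),
        "n_used": int(len(kept)),
        "excluded_zero_rna": excluded,
        "excluded_footprint_counts": int(counts.loc[zero_rna, "fp_count"].sum()),
        "over_cap_fraction": over_cap,
    }
    if excluded:
        log.info("excluded %d genes with footprints but no RNA signal", len(excluded))
    return states, qc


def assign_to_peaks(states: pd.DataFrame, n_max: int = 20) -> tuple[dict[int, float], dict]:
    """Distribute each gene's ribosome mass onto the straddling n-some peaks.

    A gene of density d with R bound ribosomes puts R·(1 - frac(d)) on peak
    floor(d) and R·frac(d) on peak ceil(d); an integer density puts all of R
    on that peak.  Peak 0 collects the sub-monosomal share (transcript
    copies carrying no ribosome); it is tracked for mass conservation but is
    invisible in a gradient.  Mass above ``n_max`` is pooled into the n_max
    peak and the pooled amount reported.

    Returns ``(masses, info)`` with ``masses`` mapping integer peak index
    (0..n_max) to unnormalized ribosome mass.
    """
    dens = np.asarray(states["density"], dtype=float)
    ribs = np.asarray(states["ribosomes_bound"], dtype=float)
    if np.any(dens < 0) or np.any(~np.isfinite(dens)):
        raise InvalidInputError("densities must be finite and >= 0")

    masses: dict[int, float] = {}
    pooled = 0.0
    floor = np.floor(dens).astype(int)
    frac = dens - floor
    for lo_peak, f, r in zip(floor, frac, ribs):
        for peak, mass in ((lo_peak, r * (1.0 - f)), (lo_peak + 1, r * f)):
            if mass == 0.0:
                continue
            if peak > n_max:
                pooled += mass
                peak = n_max
            masses[peak] = masses.get(peak, 0.0) + mass
    info = {"peak0_mass": masses.get(0, 0.0), "pooled_mass": pooled, "n_max": n_max}
    if pooled:
        log.info("pooled %.3g ribosomes from peaks > %d into peak %d",
                 pooled, n_max, n_max)
    return masses, info


def add_inactive(
    nsome_masses: dict[int, float],
    params: CellParams,
    include_idle: bool = True,
) -> PeakVolumes:
    """Complete the profile with the inactive-ribosome pool and normalize.

    With ``include_idle`` the inactive pool total_ribosomes·(1 - active
    fraction) is distributed: split_fraction dissociates into subunits
    (apportioned by subunit mass fraction between the 40S and 60S peaks) and
    the rest joins the monosome peak.  Without it (for conditions where the
    free-ribosome pool is unknown) only the n-some masses are normalized and
    no subunit peaks appear.  Peak 0 is dropped either way: ribosome-free
    transcripts carry no ribosomal RNA mass and are invisible at OD254.
    """
    small, large = subunit_indices(params.small_subunit_fraction)
    masses = {float(k): v for k, v in nsome_masses.items() if k >= 1}
    if include_idle:
        inactive = params.total_ribosomes * (1.0 - params.active_fraction)
        split = inactive * params.split_fraction
        masses[small] = masses.get(small, 0.0) + split * params.small_subunit_fraction
        masses[large] = masses.get(large, 0.0) + split * (1.0 - params.small_subunit_fraction)
        masses[1.0] = masses.get(1.0, 0.0) + inactive * (1.0 - params.split_fraction)
    return PeakVolumes(masses).normalized()


def render_modelled_profile(
    volumes: PeakVolumes,
    location_model: PeakLocationModel,
    width_factor: float = 0.2,
    n_points: int = 1201,
) -> ProfileTrace:
    """Render a volume vector as a synthetic gradient trace.

    Each peak becomes a Gaussian of unit-normalized area ``volume`` at its
    predicted position, with sigma = width_factor × local inter-peak
    spacing, on a regular grid spanning all peaks ±4σ.  Total area is 1
    within grid-integration error.
    """
    if not volumes.is_normalized():
        raise InvalidInputError("volumes must be normalized before rendering")
    if not width_factor > 0:
        raise InvalidInputError("width_factor must be > 0")
    indices = volumes.indices
    mus = predict_positions(location_model, indices)
    if mus.size >= 2:
        sigmas = width_factor * local_spacings(mus)
    else:
        # lone peak: fall back to the model's monosome--disome spacing
        sigmas = np.array([width_factor * location_model.a * math.log(2.0)])
    grid = np.linspace(mus[0] - 4 * sigmas[0], mus[-1] + 4 * sigmas[-1], n_points)
    y = np.zeros_like(grid)
    for vol, mu, sigma in zip(volumes.values_array, mus, sigmas):
        y += vol * _gauss(grid, mu, sigma)
    return ProfileTrace(position=grid, absorbance=y)


def model_counts(
    counts: pd.DataFrame,
    params: CellParams,
    *,
    n_max: int = 20,
    include_idle: bool = True,
    reference_rna: pd.DataFrame | None = None,
) -> tuple[PeakVolumes, dict]:
    """Full counts -> peak-volume pipeline.

    ``reference_rna`` substitutes the RNA column from a second table (joined
    on gene_id) before modelling — the recourse when a dataset's own RNA-Seq
    data are suspected of transcript-selective biases.  Returns the
    normalized volume vector and a QC dictionary.
    """
    counts = validate_counts(counts)
    qc_extra: dict = {}
    if reference_rna is not None:
        ref = reference_rna.loc[:, ["gene_id", "rna_count"]]
        merged = counts.drop(columns="rna_count").merge(ref, on="gene_id", how="inner")
        qc_extra["reference_rna_genes_dropped"] = int(len(counts) - len(merged))
        counts = merged
    states, qc = compute_states(counts, params)
    masses, info = assign_to_peaks(states, n_max=n_max)
    volumes = add_inactive(masses, params, include_idle=include_idle)
    qc.update(info)
    qc.update(qc_extra)
    return volumes, qc
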