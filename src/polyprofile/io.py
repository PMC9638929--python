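"""File formats, run configuration, and the end-to-end pipeline.

All tabular outputs are plain TSV with a ``#``-prefixed metadata header
(tool version, config hash, seed where applicable) so results are diffable,
re-loadable and carry their provenance.
"""
from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import RmsdNull, fit_null, rmsd, rmsd_pvalue
from .errors import InvalidInputError
from .fitting import DebrisBaseline, GaussianPeak, ProfileModel
from .model import CellParams, model_counts, render_modelled_profile, validate_counts
from .peaks import (PeakLocationModel, ProfileTrace, assign_default_indices,
                    detect_peaks, fit_location_model)
from .volumes import PeakVolumes

log = logging.getLogger(__name__)

#: column-name aliases accepted in count tables
_LENGTH_ALIASES = ("length_nt", "length", "cds_length")


def metadata_header(**fields) -> str:
    """``#``-prefixed provenance block for output files."""
    lines = [f"# polyprofile {__version__}"]
    lines += [f"# {key}: {value}" for key, value in fields.items()]
    return "\n".join(lines) + "\n"


def config_hash(config) -> str:
    """Short stable digest of a configuration object or mapping.

    Output locations are excluded so identical analyses written to different
    directories produce byte-identical result files.
    """
    data = (asdict(config) if hasattr(config, "__dataclass_fields__")
            else dict(config))
    data.pop("outdir", None)
    payload = repr(sorted(data.items()))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sniff_sep(sample: str) -> str:
    for line in sample.splitlines():
        if line and not line.startswith("#"):
            return "\t" if line.count("\t") >= line.count(",") else ","
    return "\t"


def _read_table(path, **kw) -> pd.DataFrame:
    """CSV/TSV reader: delimiter sniffed, floats parsed to full precision."""
    if isinstance(path, _io.StringIO):
        sample = path.getvalue()
        path.seek(0)
    else:
        with open(path) as fh:
            sample = fh.read(4096)
    try:
        return pd.read_csv(path, sep=_sniff_sep(sample), comment="#",
                           float_precision="round_trip", **kw)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc


def read_trace(path, has_header: bool | str = "auto") -> ProfileTrace:
    """Read a two-column (position, absorbance) trace file.

    CSV or TSV; with ``has_header="auto"`` the first line is treated as a
    header unless both fields parse as numbers.  Monotonicity violations are
    rejected naming the offending data row.
    """
    if has_header == "auto":
        with open(path) as fh:
            first = fh.readline()
            while first.startswith("#"):
                first = fh.readline()
        tokens = first.replace(",", " ").replace("\t", " ").split()
        try:
            [float(t) for t in tokens]
            has_header = False
        except ValueError:
            has_header = True
    df = _read_table(path, header=0 if has_header else None)
    if has_header:
        missing = [c for c in ("position", "absorbance") if c not in df.columns]
        if missing:
            raise InvalidInputError(f"{path} missing columns {missing}")
        pos, absn = df["position"], df["absorbance"]
    else:
        if df.shape[1] < 2:
            raise InvalidInputError(f"{path} needs two columns, found {df.shape[1]}")
        pos, absn = df.iloc[:, 0], df.iloc[:, 1]
    return ProfileTrace(position=np.asarray(pos, float),
                        absorbance=np.asarray(absn, float))


def write_trace(trace: ProfileTrace, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(**(metadata or {})))
        pd.DataFrame({"position": trace.position,
                      "absorbance": trace.absorbance}).to_csv(
            fh, sep="\t", index=False, float_format="%.17g")


def read_counts(path, rpkm: bool = False, depth: float = 1e6) -> pd.DataFrame:
    """Read a per-gene count table (gene_id, length, fp_count, rna_count).

    With ``rpkm=True`` both count columns are interpreted as RPKM and
    converted to effective counts (RPKM × length_kb × depth/1e6).  All
    downstream quantities are ratios, so any positive ``depth`` yields the
    same modelled profile.
    """
    df = _read_table(path)
    for alias in _LENGTH_ALIASES:
        if alias in df.columns:
            df = df.rename(columns={alias: "length_nt"})
            break
    df = validate_counts(df)
    if rpkm:
        length_kb = df["length_nt"] / 1000.0
        for col in ("fp_count", "rna_count"):
            df[col] = df[col] * length_kb * depth / 1e6
    return df


def read_volumes(path) -> PeakVolumes:
    df = _read_table(path)
    if not {"index", "volume"} <= set(df.columns):
        raise InvalidInputError(f"{path} must have columns index, volume")
    return PeakVolumes(dict(zip(df["index"].astype(float), df["volume"].astype(float))))


def write_volumes(volumes: PeakVolumes, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(**(metadata or {})))
        pd.DataFrame({"index": volumes.indices,
                      "volume": volumes.values_array}).to_csv(
            fh, sep="\t", index=False, float_format="%.17g")


def write_model(model: ProfileModel, path, metadata: dict | None = None) -> None:
    """Serialise a fitted profile model to a flat, diffable TSV."""
    meta = dict(metadata or {})
    bg = model.background
    meta["background"] = (f"amplitude={bg.amplitude!r} decay={bg.decay!r} "
                          f"slope={bg.slope!r} offset={bg.offset!r}")
    if model.rms_error is not None:
        meta["rms_error"] = repr(model.rms_error)
    with open(path, "w") as fh:
        fh.write(metadata_header(**meta))
        pd.DataFrame([{"index": p.index, "mu": p.mu, "sigma": p.sigma, "s": p.s}
                      for p in model.peaks]).to_csv(
            fh, sep="\t", index=False, float_format="%.17g")


def read_model(path) -> ProfileModel:
    background = DebrisBaseline()
    rms_error = None
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("# background:"):
            kv = dict(tok.split("=") for tok in line.split(":", 1)[1].split())
            background = DebrisBaseline(**{k: float(v) for k, v in kv.items()})
        elif line.startswith("# rms_error:"):
            rms_error = float(line.split(":", 1)[1])
    df = _read_table(_io.StringIO(text))
    peaks = [GaussianPeak(index=r["index"], mu=r["mu"], sigma=r["sigma"], s=r["s"])
             for _, r in df.iterrows()]
    return ProfileModel(peaks=peaks, background=background, rms_error=rms_error)


def write_null(null: RmsdNull, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(**(metadata or {})))
        yaml.safe_dump({"mu": null.mu, "sd": null.sd, "n_pairs": null.n_pairs}, fh)


def read_null(path) -> RmsdNull:
    with open(path) as fh:
        data = yaml.safe_load("\n".join(
            ln for ln in fh.read().splitlines() if not ln.startswith("#")))
    try:
        return RmsdNull(mu=float(data["mu"]), sd=float(data["sd"]),
                        n_pairs=int(data["n_pairs"]))
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"{path} is not a null-parameter file: {exc}") from exc


@dataclass
class RunConfig:
    """Fully explicit configuration for the end-to-end pipeline.

    Defaults are materialized here (and logged at run time) so a resolved
    config never carries implicit state.
    """

    counts: str = ""
    preset: str = "yeast"
    params_overrides: dict = field(default_factory=dict)
    n_max: int = 20
    min_run: int = 4
    width_factor: float = 0.2
    include_idle: bool = True
    rpkm: bool = False
    location_a: float = 15.0
    location_b: float = 30.0
    reference_rna: str | None = None
    reference_trace: str | None = None
    reference_volumes: str | None = None
    null_file: str | None = None
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """counts -> states -> peak assignment -> idle completion -> rendering.

    Writes ``volumes.tsv``, ``modelled_trace.tsv`` and ``report.yaml`` into
    ``config.outdir``; when a reference volume table is supplied the report
    gains an RMSD and its P-value against the configured (or packaged) null.
    Returns the report as a dictionary.
    """
    if not config.counts:
        raise InvalidInputError("config.counts is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config)
    log.info("resolved config (hash %s): %s", digest, asdict(config))

    counts = read_counts(config.counts, rpkm=config.rpkm)
    reference_rna = (read_counts(config.reference_rna, rpkm=config.rpkm)
                     if config.reference_rna else None)
    params = CellParams.preset(config.preset, **config.params_overrides)
    volumes, qc = model_counts(counts, params, n_max=config.n_max,
                               include_idle=config.include_idle,
                               reference_rna=reference_rna)

    if config.reference_trace:
        ref_trace = read_trace(config.reference_trace)
        detected = detect_peaks(ref_trace, min_run=config.min_run)
        positions, indices = assign_default_indices(detected)
        location = fit_location_model(positions, indices)
    else:
        location = PeakLocationModel(a=config.location_a, b=config.location_b)
    rendered = render_modelled_profile(volumes, location,
                                       width_factor=config.width_factor)

    meta = {"config_hash": digest, "preset": config.preset}
    write_volumes(volumes, outdir / "volumes.tsv", metadata=meta)
    write_trace(rendered, outdir / "modelled_trace.tsv", metadata=meta)

    report: dict = {"config_hash": digest, "qc": _plain(qc),
                    "location_model": {"a": location.a, "b": location.b}}
    if config.reference_volumes:
        reference = read_volumes(config.reference_volumes)
        value = rmsd(volumes, reference)
        report["rmsd_to_reference"] = value
        null = _resolve_null(config)
        report["p_value"] = rmsd_pvalue(value, null)
        report["null"] = {"mu": null.mu, "sd": null.sd, "n_pairs": null.n_pairs}
    with open(outdir / "report.yaml", "w") as fh:
        fh.write(metadata_header(config_hash=digest))
        yaml.safe_dump(report, fh)
    log.info("QC summary: %s", report["qc"])
    return report


def _resolve_null(config: RunConfig) -> RmsdNull:
    if config.null_file:
        return read_null(config.null_file)
    from .synthetic import default_known_good
    log.info("no null file configured; using the packaged known-good collection")
    return fit_null(default_known_good())


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
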