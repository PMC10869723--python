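"""End-to-end orchestration: manifests, configuration, study runs.

A study is a set of specimens, each with one frame directory per gel-pad
angle (``<specimen>/ga<angle>/frame<k>.tif``).  The pipeline runs
orientation estimation, ROI placement, MGV extraction, the sweep
homogeneity screen, and the sine/linear spatial-gain fits, and emits the
tidy per-specimen table that downstream mixed-effects analyses consume.

Also packages the specimen-overview fixture of the ex-vivo bovine study
this method was validated on (ten muscle codes, 24 animals, 51 specimens,
ages known for 12 animals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import fitting, orientation, phantom
from .frames import Frame, ROISpec, read_frame

logger = logging.getLogger("spatialgain")

MUSCLE_CODES = ("ecr", "edc", "edl", "fcr", "fhl", "fl", "ft", "pso", "sch", "ssp")

MANIFEST_COLUMNS = ("specimen_id", "muscle", "animal_id", "age", "directory")


class ManifestError(ValueError):
    """Raised for malformed study manifests."""


# ---------------------------------------------------------------------------
# specimen-overview fixture (ex-vivo bovine validation study)

_ANIMALS = (
    "A0", "B8", "C0", "C5", "D8", "F1", "G2", "H0", "H7", "J1", "J6", "K9",
    "N6", "O2", "P0", "P3", "R6", "S7", "S9", "T8", "U1", "V5", "V9", "Y8",
)

# rows: muscle code; columns: animals above; entry = specimens analyzed
_COUNTS = {
    "ecr": (0, 0, 0, 1, 1, 0, 0, 0, 1, 0, 1, 0, 1, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0),
    "edc": (0, 0, 0, 1, 1, 0, 0, 0, 1, 0, 1, 1, 1, 1, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0),
    "edl": (0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "fcr": (0, 0, 0, 1, 1, 0, 0, 0, 1, 0, 1, 1, 1, 1, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0),
    "fhl": (0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 1, 0),
    "fl":  (0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 1, 0),
    "ft":  (0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 1, 0),
    "pso": (0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 1, 0, 0, 0),
    "sch": (1, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "ssp": (0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1),
}

#: the twelve ages (years) made available by the abattoir; the published
#: table does not state which animals they belong to
_KNOWN_AGES = (6.08, 3.34, 8.22, 5.52, 6.34, 6.42, 4.99, 5.11, 4.43, 8.22, 6.97, 5.11)


@dataclass(frozen=True)
class Table1Fixture:
    """Specimen counts per muscle and animal, plus the known ages."""

    counts: pd.DataFrame  # index: muscle code, columns: animal id
    ages: tuple[float, ...]


def load_table1() -> Table1Fixture:
    """The packaged specimen-overview fixture (51 bovine specimens)."""
    counts = pd.DataFrame(
        {a: [ _COUNTS[m][i] for m in MUSCLE_CODES ] for i, a in enumerate(_ANIMALS)},
        index=list(MUSCLE_CODES),
    )
    return Table1Fixture(counts=counts, ages=_KNOWN_AGES)


def table1_stats(
    fixture: Table1Fixture,
) -> tuple[int, float, tuple[float, float]]:
    """Total specimen count, mean age (2 decimals) and age range."""
    total = int(fixture.counts.to_numpy().sum())
    ages = np.asarray(fixture.ages, dtype=float)
    return total, round(float(ages.mean()), 2), (float(ages.min()), float(ages.max()))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters, all with study-wide scope.

    ``fit_max_abs_fpa_deg`` restricts the fits to the angle range the
    method is recommended for (|FPA| <= 30 degrees).
    """

    roi_width: int = 400
    roi_height: int = 200
    roi_offset_px: int = 80
    fit_max_abs_fpa_deg: float = 30.0
    homogeneity_p_threshold: float = 0.20
    gel_pad_angles_deg: tuple[float, ...] = phantom.DEFAULT_GEL_PAD_ANGLES
    epimysium_search_halfwidth_deg: float = 30.0
    fascicle_search_halfwidth_deg: float = 45.0
    epimysium_min_peak_ratio: float = 1.5
    fascicle_min_anisotropy: float = 2.0
    image_format: str = "tif"

    def roi_template(self) -> ROISpec:
        return ROISpec(
            center_x=0.0, center_y=0.0, width=self.roi_width, height=self.roi_height
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "gel_pad_angles_deg" in d:
            d["gel_pad_angles_deg"] = tuple(d["gel_pad_angles_deg"])
        return cls(**d)


# ---------------------------------------------------------------------------
# manifests


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a study manifest CSV.

    Columns: specimen_id, muscle (ten-muscle vocabulary), animal_id,
    age (years, may be empty — never imputed), directory (sweep root,
    relative paths resolved against the manifest location).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"specimen_id": str, "animal_id": str})
    return validate_manifest(df, base_dir=path.parent)


def validate_manifest(df: pd.DataFrame, base_dir: Path | None = None) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest lacks columns: {missing}")
    bad = sorted(set(df["muscle"]) - set(MUSCLE_CODES))
    if bad:
        raise ManifestError(
            f"unknown muscle codes {bad}; expected one of {MUSCLE_CODES}"
        )
    df = df.copy()
    if base_dir is not None:
        df["directory"] = [
            str((base_dir / d)) if not Path(d).is_absolute() else str(d)
            for d in df["directory"]
        ]
    return df


# ---------------------------------------------------------------------------
# per-frame analysis


def _specimen_frames(
    directory: Path, config: AnalysisConfig, specimen_id: str
) -> list[Frame]:
    frames: list[Frame] = []
    for ga in config.gel_pad_angles_deg:
        ga_dir = directory / f"ga{int(round(ga))}"
        paths = sorted(ga_dir.glob(f"frame*.{config.image_format}"))
        if not paths:
            raise FileNotFoundError(f"missing sweep directory or frames: {ga_dir}")
        for k, p in enumerate(paths):
            frames.append(
                read_frame(p, gel_pad_deg=ga, frame_index=k, specimen_id=specimen_id)
            )
    return frames


def analyze_frame(
    frame: Frame, config: AnalysisConfig
) -> dict:
    """Angles, ROI and MGV for a single frame."""
    epi = orientation.estimate_epimysium_angle(
        frame,
        search_halfwidth_deg=config.epimysium_search_halfwidth_deg,
        min_peak_ratio=config.epimysium_min_peak_ratio,
    )
    roi = orientation.place_roi(
        frame,
        config.roi_template(),
        offset_px=config.roi_offset_px,
        epimysium_deg=epi,
    )
    fas = orientation.estimate_fascicle_angle(
        frame,
        roi,
        search_halfwidth_deg=config.fascicle_search_halfwidth_deg,
        min_anisotropy=config.fascicle_min_anisotropy,
    )
    ang = orientation.derive_angles(fas, epi, frame.gel_pad_deg)
    mgv = orientation.compute_mgv(frame, roi)
    return {
        "specimen": frame.specimen_id,
        "gel_pad_deg": frame.gel_pad_deg,
        "frame": frame.frame_index,
        "epimysium_deg": ang.epimysium_deg,
        "fascicle_deg": ang.fascicle_deg,
        "alpha_deg": ang.alpha_deg,
        "fpa_deg": ang.fpa_deg,
        "ROICx": roi.center_x,
        "ROICy": roi.center_y,
        "MGV": mgv,
    }


def analyze_frames(
    frames: list[Frame], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-frame orientation/ROI/MGV table for a list of frames."""
    config = config or AnalysisConfig()
    return pd.DataFrame([analyze_frame(f, config) for f in frames])


# ---------------------------------------------------------------------------
# per-specimen fitting


def _qq_table(residuals: np.ndarray) -> pd.DataFrame:
    """Observed vs normal theoretical quantiles of residuals."""
    r = np.sort(np.asarray(residuals, dtype=float))
    n = r.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"theoretical_q": theo, "observed_q": r})


def fit_specimen(
    frame_table: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[dict, dict]:
    """Fit both model families to one specimen's per-frame table.

    Returns (summary-row dict, diagnostics dict with residual/QQ tables).
    """
    config = config or AnalysisConfig()
    sub = frame_table[
        frame_table["fpa_deg"].abs() <= config.fit_max_abs_fpa_deg
    ]
    obs = fitting.observations_from_arrays(
        sub["fpa_deg"].to_numpy(), sub["MGV"].to_numpy()
    )
    sine = fitting.fit_sine(obs)
    linear = fitting.fit_linear(obs)
    comp = fitting.compare_models(sine, linear)
    homog = orientation.check_sweep_homogeneity(
        list(
            zip(
                frame_table["frame"].to_numpy(),
                frame_table["epimysium_deg"].to_numpy(),
                frame_table["MGV"].to_numpy(),
            )
        ),
        p_threshold=config.homogeneity_p_threshold,
    )
    summary = {
        "n_obs": sine.n,
        "alpha_deg_mean": float(frame_table["alpha_deg"].mean()),
        "roicy_mean": float(frame_table["ROICy"].mean()),
        "mgv00_sine": sine.beta0,
        "mgv00_linear": linear.beta0,
        "beta1_sine": sine.beta1,
        "beta1_linear": linear.beta1,
        "teg": linear.teg,
        "adjusted_r2_sine": sine.adjusted_r2,
        "adjusted_r2_linear": linear.adjusted_r2,
        "aic_sine": sine.aic,
        "aic_linear": linear.aic,
        "preferred_model": comp.preferred,
        "homogeneity_pass": homog.passed,
    }
    residual_table = pd.DataFrame(
        {
            "fpa_deg": sub["fpa_deg"].to_numpy(),
            "mgv": sub["MGV"].to_numpy(),
            "fitted_sine": sine.fitted,
            "residual_sine": sine.residuals,
            "fitted_linear": linear.fitted,
            "residual_linear": linear.residuals,
        }
    )
    diagnostics = {
        "residuals": residual_table,
        "qq_sine": _qq_table(sine.residuals),
        "qq_linear": _qq_table(linear.residuals),
    }
    return summary, diagnostics


def fit_specimens(
    frame_table: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-specimen summary table from a pooled per-frame table."""
    config = config or AnalysisConfig()
    meta = {}
    if manifest is not None:
        meta = {
            str(r.specimen_id): r for r in manifest.itertuples(index=False)
        }
    rows, diagnostics = [], {}
    for specimen, grp in frame_table.groupby("specimen", sort=True):
        summary, diag = fit_specimen(grp, config)
        row = {"specimen": specimen}
        m = meta.get(str(specimen))
        row["muscle"] = getattr(m, "muscle", None)
        row["animal_id"] = getattr(m, "animal_id", None)
        row["age"] = getattr(m, "age", np.nan)
        row.update(summary)
        rows.append(row)
        diagnostics[specimen] = diag
    return pd.DataFrame(rows), diagnostics


def ensemble_comparison(frame_table: pd.DataFrame, config: AnalysisConfig | None = None):
    """Grand-ensemble sine-vs-linear comparison over all pooled raw
    observations (diagnostic only; no per-specimen intercepts)."""
    config = config or AnalysisConfig()
    sub = frame_table[frame_table["fpa_deg"].abs() <= config.fit_max_abs_fpa_deg]
    obs = fitting.observations_from_arrays(
        sub["fpa_deg"].to_numpy(), sub["MGV"].to_numpy()
    )
    sine = fitting.fit_sine(obs)
    linear = fitting.fit_linear(obs)
    return sine, linear, fitting.compare_models(sine, linear)


# ---------------------------------------------------------------------------
# end-to-end


@dataclass(frozen=True)
class PipelineResult:
    """Outputs of one end-to-end study run."""

    frame_table: pd.DataFrame
    summary: pd.DataFrame
    diagnostics: dict
    flagged: tuple[tuple[str, str], ...]  # (specimen_id, reason)


def run_pipeline(
    manifest: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> PipelineResult:
    """Run orientation -> MGV -> homogeneity -> fits for a whole study.

    Specimens whose sweeps are missing or unreadable are flagged and the
    run continues; the summary has one row per successfully analyzed
    specimen.  Deterministic given identical inputs.
    """
    config = config or AnalysisConfig()
    manifest = validate_manifest(manifest)
    if manifest.empty:
        logger.warning("empty manifest: nothing to analyze")
        return PipelineResult(
            frame_table=pd.DataFrame(),
            summary=pd.DataFrame(),
            diagnostics={},
            flagged=(),
        )
    frame_rows: list[pd.DataFrame] = []
    flagged: list[tuple[str, str]] = []
    for row in manifest.itertuples(index=False):
        specimen = str(row.specimen_id)
        try:
            frames = _specimen_frames(Path(row.directory), config, specimen)
            frame_rows.append(analyze_frames(frames, config))
        except Exception as exc:  # noqa: BLE001 - flag and continue
            logger.warning("specimen %s skipped: %s", specimen, exc)
            flagged.append((specimen, str(exc)))
    frame_table = (
        pd.concat(frame_rows, ignore_index=True) if frame_rows else pd.DataFrame()
    )
    if frame_table.empty:
        return PipelineResult(frame_table, pd.DataFrame(), {}, tuple(flagged))
    summary, diagnostics = fit_specimens(frame_table, manifest, config)
    return PipelineResult(frame_table, summary, diagnostics, tuple(flagged))


def simulate_study(
    out_dir: str | Path,
    n_specimens: int = 10,
    seed: int = 0,
    pennation_choices: tuple[float, ...] = (2.0, 7.0, 12.0, 17.0),
    frames_per_sweep: int = 3,
    image_format: str = "tif",
) -> pd.DataFrame:
    """Write a synthetic study (frames + manifest + ground truth) to disk.

    Each specimen gets a phantom with a pennation angle cycled through
    ``pennation_choices`` and its own sub-seed; muscles cycle through the
    ten-muscle vocabulary; two specimens share each animal, and every
    second animal has a known age.  Returns the manifest DataFrame (also
    written as ``manifest.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    truth_tables = []
    for i in range(n_specimens):
        specimen = f"S{i:02d}"
        alpha = pennation_choices[i % len(pennation_choices)]
        cfg = phantom.PhantomConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            pennation_deg=alpha,
            frames_per_sweep=frames_per_sweep,
        )
        sweep = phantom.render_sweepset(cfg, specimen_id=specimen)
        phantom.write_sweepset(sweep, out_dir, image_format=image_format)
        truth_tables.append(sweep.truth_table())
        rows.append(
            {
                "specimen_id": specimen,
                "muscle": MUSCLE_CODES[i % len(MUSCLE_CODES)],
                "animal_id": f"A{i // 2:02d}",
                "age": round(4.0 + 4.0 * ((i // 2) % 5) / 4.0, 2)
                if (i // 2) % 2 == 0
                else np.nan,
                "directory": specimen,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.concat(truth_tables, ignore_index=True).to_csv(
        out_dir / "truth.csv", index=False
    )
    AnalysisConfig(image_format=image_format).to_yaml(out_dir / "config.yaml")
    return validate_manifest(manifest, base_dir=out_dir)
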