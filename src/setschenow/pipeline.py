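"""End-to-end orchestration: CSV/config in, report tables out.

The pipeline composes the stages in their scientific order — Beer-Lambert
calibration, quantification of saturated samples, the smoothing fit of
total solubility, the SIT ionization correction, activity coefficients and
Setschenow fits — and adds the replicate-comparison statistics (one-way
ANOVA with Tukey's HSD).  Every number written to a report is produced by
exactly one upstream operation; the writers only format.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .calibration import (
    CalibrationCurve,
    aggregate_replicates,
    fit_calibration,
    pick_peak,
    quantify,
    Spectrum,
)
from .exceptions import ConfigError, InsufficientDataError
from .ionization import (
    NeutralSolubilityResult,
    SITParams,
    correct_total_solubility,
)
from .solubility import (
    SmoothingParams,
    fit_total_solubility,
    salting_out_percent,
)
from .synthetic import SimulatedDataset, make_paper_like_truth, simulate_experiment
from .units import AcidSpec, Medium, SolubilityPoint, WATER

__all__ = [
    "RunConfig",
    "ComparisonResult",
    "AnalysisResult",
    "load_config",
    "analyze_dataset",
    "compare_conditions",
    "run_pipeline",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One-way ANOVA + Tukey HSD across condition groups for one acid."""

    acid: str
    groups: tuple[str, ...]
    anova_F: float
    anova_p: float
    pairwise: tuple[tuple[str, str, float, bool], ...]  # (A, B, p_adj, sig)
    alpha: float = 0.05


def compare_conditions(
    replicate_sets: list[tuple[str, list[float]]],
    acid: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """One-way ANOVA followed by Tukey's multiple-comparison test.

    Significance is declared at adjusted p < ``alpha`` (default 0.05).
    """
    if len(replicate_sets) < 2:
        raise InsufficientDataError("need >= 2 groups to compare")
    for label, values in replicate_sets:
        if len(values) < 2:
            raise InsufficientDataError(
                f"group {label!r} has fewer than 2 replicates"
            )
    labels = [label for label, _ in replicate_sets]
    data = [np.asarray(v, dtype=float) for _, v in replicate_sets]
    if all(np.ptp(d) == 0 for d in data) and len({d[0] for d in data}) == 1:
        # identical constants in every group: no variance anywhere
        f_stat, p = 0.0, 1.0
        pairwise = tuple(
            (labels[i], labels[j], 1.0, False)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        )
        return ComparisonResult(acid, tuple(labels), f_stat, p, pairwise, alpha)
    f_stat, p = stats.f_oneway(*data)
    hsd = stats.tukey_hsd(*data)
    pairwise = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            padj = float(hsd.pvalue[i, j])
            pairwise.append((labels[i], labels[j], padj, padj < alpha))
    return ComparisonResult(
        acid, tuple(labels), float(f_stat), float(p), tuple(pairwise), alpha
    )


@dataclass
class RunConfig:
    """Parsed run configuration."""

    media: dict[str, Medium]
    acids: dict[str, AcidSpec]
    debye_a: float
    debye_b: float
    output_dir: Path
    data_csv: Path | None = None
    seed: int = 0
    model: str = "auto"
    dilution_factor: float = 1.0
    through_origin: bool = False
    lod_factor: float = 3.3
    densities: dict[str, float] = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def sit_for(self, acid: AcidSpec, medium: Medium) -> SITParams:
        if medium.b_plus is None:
            raise ConfigError(f"medium {medium.name!r} has no b_plus coefficient")
        return SITParams(
            b_plus=medium.b_plus,
            b_minus=acid.b_minus,
            debye_a=self.debye_a,
            debye_b=self.debye_b,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML or YAML run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".toml", ".tml"):
        import tomllib

        raw = tomllib.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    return _config_from_dict(raw, base=path.parent)


def _config_from_dict(raw: dict, base: Path = Path(".")) -> RunConfig:
    media: dict[str, Medium] = {"water": WATER}
    for name, spec in raw.get("media", {}).items():
        if "b_plus" not in spec:
            raise ConfigError(f"medium {name!r} is missing its b_plus coefficient")
        media[name] = Medium(
            name=name,
            b_plus=float(spec["b_plus"]),
            salt_molar_mass=float(spec.get("molar_mass", 0.0)),
        )
    acids: dict[str, AcidSpec] = {}
    for name, spec in raw.get("acids", {}).items():
        acids[name] = AcidSpec(
            name=name,
            molar_mass=float(spec["molar_mass"]),
            lambda_analytical=float(spec["lambda_analytical"]),
            pK_measured=tuple(
                (float(i), float(pk)) for i, pk in spec.get("pK", [])
            ),
            b_minus=float(spec.get("b_minus", 0.06)),
        )
    debye = raw.get("debye", {})
    run = raw.get("run", {})
    inputs = raw.get("inputs", {})
    data_csv = inputs.get("data_csv")
    return RunConfig(
        media=media,
        acids=acids,
        debye_a=float(debye.get("a", 0.4565)),
        debye_b=float(debye.get("b", 1.11)),
        output_dir=base / run.get("output_dir", "setschenow-out"),
        data_csv=(base / data_csv) if data_csv else None,
        seed=int(run.get("seed", 0)),
        model=str(run.get("model", "auto")),
        dilution_factor=float(run.get("dilution_factor", 1.0)),
        through_origin=bool(run.get("through_origin", False)),
        lod_factor=float(run.get("lod_factor", 3.3)),
        densities={k: float(v) for k, v in raw.get("densities", {}).items()},
        raw=raw,
    )


@dataclass
class AnalysisResult:
    """All per-acid pipeline outputs, keyed by medium name where relevant."""

    acid: AcidSpec
    calibration: CalibrationCurve
    water_point: SolubilityPoint
    points: dict[str, list[SolubilityPoint]]
    smoothing: dict[str, SmoothingParams]
    correction: dict[str, NeutralSolubilityResult]
    salting_out: dict[str, list[tuple[float, float]]]
    comparisons: dict[str, ComparisonResult]


def _read_long_csv(path: Path, acids: dict[str, AcidSpec]) -> pd.DataFrame:
    """Read the long-format input CSV, collapsing spectra to peak readings."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ConfigError(f"unparseable CSV {path}: {exc}") from exc
    required_any = {"absorbance_at_peak", "absorbance"}
    if not required_any & set(df.columns):
        raise ConfigError(
            f"{path}: need an 'absorbance_at_peak' or spectral "
            "'wavelength_nm'/'absorbance' column pair"
        )
    if "absorbance_at_peak" in df.columns:
        return df
    keys = ["acid", "role", "medium", "ionic_strength_molal", "replicate"]
    rows = []
    for key, grp in df.groupby(keys, sort=False):
        acid_name = key[0]
        if acid_name not in acids:
            raise ConfigError(f"acid {acid_name!r} in data but not in config")
        lam = acids[acid_name].lambda_analytical
        spectrum = Spectrum(
            grp["wavelength_nm"].to_numpy(), grp["absorbance"].to_numpy()
        )
        _, a_max = pick_peak(spectrum, (lam - 5.0, lam + 5.0))
        rows.append(dict(zip(keys, key)) | {"absorbance_at_peak": a_max})
    return pd.DataFrame(rows)


def analyze_frame(
    df: pd.DataFrame,
    acid: AcidSpec,
    media: dict[str, Medium],
    model: str = "auto",
    dilution_factor: float = 1.0,
    through_origin: bool = False,
    lod_factor: float = 3.3,
    sit_by_medium: dict[str, SITParams] | None = None,
    pk_by_medium: dict[str, tuple[tuple[float, float], ...]] | None = None,
) -> AnalysisResult:
    """Run the full analysis for one acid from a pre-picked long frame.

    The frame needs columns ``role`` (standard|sample), ``medium``,
    ``ionic_strength_molal``, ``replicate`` and ``absorbance_at_peak``;
    standard rows carry the standard molality in ``ionic_strength_molal``.
    """
    std = df[df["role"] == "standard"]
    curve = fit_calibration(
        list(zip(std["ionic_strength_molal"], std["absorbance_at_peak"])),
        through_origin=through_origin,
        lod_factor=lod_factor,
    )

    samples = df[df["role"] == "sample"]
    for name in samples["medium"].unique():
        if name not in media:
            raise ConfigError(f"unknown medium {name!r}: not declared in config")

    points: dict[str, list[SolubilityPoint]] = {}
    replicate_values: dict[str, list[tuple[str, list[float]]]] = {}
    water_point = None
    for (med_name, m_salt), grp in samples.groupby(
        ["medium", "ionic_strength_molal"]
    ):
        vals = [
            quantify(a, curve, dilution_factor).value
            for a in grp["absorbance_at_peak"]
        ]
        mean, sd, _ = aggregate_replicates(vals)
        point = SolubilityPoint(
            medium=media[med_name],
            m_salt=float(m_salt),
            S_T=mean,
            replicates=list(vals),
            sd=sd,
        )
        label = "water" if med_name == "water" else f"{med_name} {m_salt:g}"
        if med_name == "water":
            water_point = point
        else:
            points.setdefault(med_name, []).append(point)
        replicate_values.setdefault(med_name, []).append((label, vals))
    if water_point is None:
        raise ConfigError("no pure-water sample rows found")

    smoothing, correction, salting, comparisons = {}, {}, {}, {}
    for med_name, pts in points.items():
        pts = sorted(pts, key=lambda p: p.m_salt)
        all_pts = [water_point] + pts
        smoothing[med_name] = fit_total_solubility(all_pts, model=model)
        acid_here = acid
        if pk_by_medium is not None:
            acid_here = AcidSpec(
                name=acid.name,
                molar_mass=acid.molar_mass,
                lambda_analytical=acid.lambda_analytical,
                pK_measured=pk_by_medium.get(med_name, ()),
                b_minus=acid.b_minus,
            )
        sit = sit_by_medium.get(med_name) if sit_by_medium else None
        correction[med_name] = correct_total_solubility(
            all_pts, acid_here, media[med_name], model=model, sit=sit
        )
        salting[med_name] = [
            (p.m_salt, salting_out_percent(water_point.S_T, p.S_T)) for p in pts
        ]
        groups = [("water", water_point.replicates)] + [
            (f"{med_name} {p.m_salt:g}", p.replicates) for p in pts
        ]
        if all(len(v) >= 2 for _, v in groups):
            comparisons[med_name] = compare_conditions(groups, acid=acid.name)

    return AnalysisResult(
        acid=acid,
        calibration=curve,
        water_point=water_point,
        points=points,
        smoothing=smoothing,
        correction=correction,
        salting_out=salting,
        comparisons=comparisons,
    )


def analyze_dataset(
    dataset: SimulatedDataset, model: str = "auto"
) -> AnalysisResult:
    """Run the full analysis on an in-memory simulated dataset."""
    rows = [
        {
            "acid": dataset.truth.acid.name,
            "role": "standard",
            "medium": "water",
            "ionic_strength_molal": mol,
            "replicate": rep,
            "absorbance_at_peak": a,
        }
        for mol, a, rep in dataset.standards
    ] + [
        {
            "acid": dataset.truth.acid.name,
            "role": "sample",
            "medium": med,
            "ionic_strength_molal": m_salt,
            "replicate": rep,
            "absorbance_at_peak": a,
        }
        for med, m_salt, rep, a in dataset.samples
    ]
    media = {"water": WATER} | {md.name: md for md in dataset.media}
    return analyze_frame(
        pd.DataFrame(rows),
        acid=dataset.truth.acid,
        media=media,
        model=model,
        dilution_factor=dataset.dilution,
        sit_by_medium={
            name: p for name, p in dataset.truth.sit.items()
        } or None,
        pk_by_medium=dataset.pk_measured,
    )


def _write_reports(
    results: dict[str, AnalysisResult], outdir: Path, config_hash: str, seed: int
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cal_rows, sol_rows, fit_rows, neutral_rows, act_rows, salt_rows, cmp_rows = (
        [], [], [], [], [], [], []
    )
    for name, res in results.items():
        c = res.calibration
        cal_rows.append(
            dict(acid=name, slope=c.slope, intercept=c.intercept,
                 r_squared=c.r_squared, lod=c.lod,
                 range_min=c.range[0], range_max=c.range[1])
        )
        all_media_points = {"water": [res.water_point]} | res.points
        for med, pts in all_media_points.items():
            for p in pts:
                sol_rows.append(
                    dict(acid=name, medium=med, m_salt=p.m_salt,
                         S_T=p.S_T, sd=p.sd, n=len(p.replicates))
                )
        for med, sp in res.smoothing.items():
            se = sp.stderr
            fit_rows.append(
                dict(acid=name, medium=med, model=sp.model,
                     log_S_T0=sp.log_S_T0, a_0=sp.a_0, a_inf=sp.a_inf,
                     se_log_S_T0=se[0], se_a_0=se[1], se_a_inf=se[2],
                     rss=sp.rss, f_pvalue=sp.f_pvalue)
            )
        for med, corr in res.correction.items():
            for m_salt, spec in corr.speciation:
                ion = {i.ionic_strength: i for i in corr.ionization}
                pk_i = ion[m_salt].pK_I if m_salt in ion else float("nan")
                neutral_rows.append(
                    dict(acid=name, medium=med, m_salt=m_salt, pK_I=pk_i,
                         h=spec.h, s0=spec.s0, S_T=spec.S_T)
                )
            f = corr.setschenow
            for ap in corr.activity:
                act_rows.append(
                    dict(acid=name, medium=med, m_salt=ap.m_salt,
                         log_gamma=ap.log_gamma, gamma=ap.gamma)
                )
            act_rows.append(
                dict(acid=name, medium=med, m_salt=float("nan"),
                     log_gamma=float("nan"), gamma=float("nan"),
                     model=f.model, k_0=f.k_0, k_inf=f.k_inf,
                     se_k_0=f.stderr[0], se_k_inf=f.stderr[1],
                     pK0=corr.pK0, n_iter=corr.n_iter)
            )
        for med, rows in res.salting_out.items():
            for m_salt, pct in rows:
                salt_rows.append(
                    dict(acid=name, medium=med, m_salt=m_salt,
                         salting_out_percent=pct)
                )
        for med, cmp_res in res.comparisons.items():
            for a, b, padj, sig in cmp_res.pairwise:
                cmp_rows.append(
                    dict(acid=name, medium=med, group_a=a, group_b=b,
                         anova_F=cmp_res.anova_F, anova_p=cmp_res.anova_p,
                         p_adj=padj, significant=sig)
                )
    pd.DataFrame(cal_rows).to_csv(outdir / "calibration_report.csv", index=False)
    pd.DataFrame(sol_rows).to_csv(outdir / "total_solubility.csv", index=False)
    pd.DataFrame(fit_rows).to_csv(outdir / "smoothing_fits.csv", index=False)
    pd.DataFrame(neutral_rows).to_csv(outdir / "neutral_species.csv", index=False)
    pd.DataFrame(act_rows).to_csv(outdir / "activity_setschenow.csv", index=False)
    pd.DataFrame(salt_rows).to_csv(outdir / "salting_out.csv", index=False)
    pd.DataFrame(cmp_rows).to_csv(outdir / "comparisons.csv", index=False)
    manifest = dict(package_version=__version__, config_sha256=config_hash, seed=seed)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_pipeline(config: RunConfig) -> dict[str, AnalysisResult]:
    """Run the full pipeline per the configuration and write report CSVs.

    With ``inputs.data_csv`` set, real data are analyzed; otherwise a
    synthetic paper-like experiment is simulated from ``run.seed``.
    """
    results: dict[str, AnalysisResult] = {}
    if config.data_csv is not None:
        df = _read_long_csv(config.data_csv, config.acids)
        for acid_name, sub in df.groupby("acid"):
            if acid_name not in config.acids:
                raise ConfigError(f"acid {acid_name!r} in data but not in config")
            acid = config.acids[acid_name]
            sit_by_medium = {
                name: config.sit_for(acid, med)
                for name, med in config.media.items()
                if not med.is_water
            }
            results[acid_name] = analyze_frame(
                sub,
                acid=acid,
                media=config.media,
                model=config.model,
                dilution_factor=config.dilution_factor,
                through_origin=config.through_origin,
                lod_factor=config.lod_factor,
                sit_by_medium=sit_by_medium,
            )
    else:
        media = [m for m in config.media.values() if not m.is_water]
        for subclass in ("hydroxybenzoic", "hydroxycinnamic"):
            truth = make_paper_like_truth(
                subclass, seed=config.seed, media=media or None
            )
            dataset = simulate_experiment(
                truth, media=media or None, seed=config.seed
            )
            results[truth.acid.name] = analyze_dataset(dataset, model=config.model)

    config_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    _write_reports(results, config.output_dir, config_hash, config.seed)
    return results
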