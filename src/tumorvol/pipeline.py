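"""End-to-end orchestration: masks -> features -> analysis report.

The analysis report mirrors the structure of a clinical volumetry study:

1. volumetry summary (medians / ranges, response prevalence, nodal mix);
2. Pearson + Spearman correlations among CATV, RTV and compactness;
3. univariate logistic regression per predictor;
4. VIF multicollinearity screen with a configurable drop rule (default:
   when both volume measures are flagged, drop CATV and keep RTV +
   compactness);
5. multivariate logistic regression on the retained predictors;
6. ROC comparison of the raw volume definitions (RTV, CATV, TCTV) with
   all pairwise DeLong tests;
7. model-assisted ROC comparison: RTV and TCTV are median-normalized onto
   CATV's scale, each patient is scored with the logistic dose-response
   model, and the three score sets are compared pairwise;
8. optional subgroup reruns of the ROC section.

All file I/O, configuration and logging live here; the statistics modules
operate on in-memory arrays.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, read_cohort, write_cohort
from .dose import TRPCoefficients, normalize_to_reference_median, trp
from .errors import ConfigurationError, SchemaError, TumorvolError
from .mask import read_mask
from .stats import correlate, delong_compare, fit_logistic, roc, vif
from .volumetry import extract_features

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "read_cohort",
    "write_cohort",
    "run_feature_extraction",
    "run_analysis",
    "write_manifest",
]

logger = logging.getLogger(__name__)

MASK_SUFFIXES = (".nii", ".nii.gz", ".nrrd")

#: predictor name -> function building the numeric model column
_PREDICTOR_BUILDERS = {
    "age": lambda df: df["age"].astype(float),
    "sex_female": lambda df: (df["sex"] == "F").astype(float),
    "interval": lambda df: df["interval"].map({"3-6wk": 0, "6-8wk": 1, ">8wk": 2}).astype(float),
    "cT4": lambda df: (df["cT"] == 4).astype(float),
    "cn_pos": lambda df: df["cn_pos"].astype(float),
    "eqd2_gt50": lambda df: (df["eqd2_gy"] > 50).astype(float),
    "chemo_fl": lambda df: (df["chemo"] == "FL").astype(float),
    "rtv_cm3": lambda df: df["rtv_cm3"].astype(float),
    "compactness": lambda df: df["compactness"].astype(float),
    "catv_cm3": lambda df: df["catv_cm3"].astype(float),
}

_PREDICTOR_SOURCE_COLUMNS = {
    "sex_female": "sex",
    "cT4": "cT",
    "eqd2_gt50": "eqd2_gy",
    "chemo_fl": "chemo",
}

VOLUME_PREDICTORS = ("rtv_cm3", "catv_cm3")


@dataclass
class AnalysisConfig:
    """Single configuration object for the whole pipeline (YAML-loadable)."""

    contraction_depth_mm: float = 1.0
    isotropize: bool = False
    alpha_beta_gy: float = 10.0
    trp_coefficients: TRPCoefficients | None = None
    model_assisted: bool = False
    vif_drop: str = "catv_cm3"
    univariate_predictors: tuple[str, ...] = (
        "age", "sex_female", "interval", "cT4", "cn_pos", "eqd2_gt50",
        "chemo_fl", "rtv_cm3", "compactness", "catv_cm3",
    )
    subgroups: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        if "trp_coefficients" in kwargs and kwargs["trp_coefficients"] is not None:
            kwargs["trp_coefficients"] = TRPCoefficients.from_mapping(kwargs["trp_coefficients"])
        if "univariate_predictors" in kwargs:
            kwargs["univariate_predictors"] = tuple(kwargs["univariate_predictors"])
        if "subgroups" in kwargs:
            kwargs["subgroups"] = tuple((s["column"], s["value"]) for s in kwargs["subgroups"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.trp_coefficients is not None:
            d["trp_coefficients"] = dataclasses.asdict(self.trp_coefficients)
        return d


@dataclass
class AnalysisReport:
    """Ordered sections of the analysis; serializable to JSON and CSVs."""

    sections: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.sections, indent=2, default=_jsonable, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_tables(self, directory: str | Path) -> list[Path]:
        """One CSV per tabular section, named after the section."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, section in self.sections.items():
            frame = _section_frame(section)
            if frame is not None:
                out = directory / f"{name}.csv"
                frame.to_csv(out, index=False)
                written.append(out)
        return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _section_frame(section) -> pd.DataFrame | None:
    if isinstance(section, pd.DataFrame):
        return section
    if isinstance(section, list) and section and isinstance(section[0], dict):
        return pd.DataFrame(section)
    return None


# --------------------------------------------------------- feature extraction


def run_feature_extraction(
    mask_dir: str | Path,
    out_csv: str | Path | None = None,
    depth_mm: float = 1.0,
    isotropize: bool = False,
) -> pd.DataFrame:
    """Extract volumetric features for every mask file in a directory.

    One row per mask (id = file stem).  Per-file failures are logged and
    recorded in the ``error`` column; the run only fails if no file could
    be processed.
    """
    mask_dir = Path(mask_dir)
    files = sorted(
        p for p in mask_dir.iterdir()
        if p.name.endswith(MASK_SUFFIXES)
    )
    if not files:
        raise SchemaError(f"no mask files (NIfTI/NRRD) found in {mask_dir}")
    rows = []
    n_failed = 0
    for path in files:
        stem = path.name
        for suf in MASK_SUFFIXES:
            if stem.endswith(suf):
                stem = stem[: -len(suf)]
                break
        row = {"id": stem}
        try:
            feats = extract_features(read_mask(path), depth_mm=depth_mm, isotropize=isotropize)
            row.update(feats.to_dict())
            row["error"] = ""
        except (TumorvolError, RuntimeError) as exc:
            logger.error("feature extraction failed for %s: %s", path.name, exc)
            row["error"] = str(exc)
            n_failed += 1
        rows.append(row)
    if n_failed == len(files):
        raise TumorvolError(f"feature extraction failed for all {len(files)} masks")
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


# ----------------------------------------------------------------- analysis


def _model_frame(cohort: Cohort, predictors) -> pd.DataFrame:
    """Numeric model columns for the predictors available in this cohort."""
    df = cohort.df
    cols = {}
    for name in predictors:
        source = _PREDICTOR_SOURCE_COLUMNS.get(name, name)
        if source in df.columns:
            cols[name] = _PREDICTOR_BUILDERS[name](df)
    return pd.DataFrame(cols)


def run_analysis(cohort: Cohort, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full statistical comparison on a cohort with features."""
    config = config or AnalysisConfig()
    if config.model_assisted and config.trp_coefficients is None:
        raise ConfigurationError(
            "model-assisted ROC stage is enabled but trp_coefficients are not configured"
        )
    df = cohort.df
    report = AnalysisReport()

    # listwise-complete subset for modelling
    model_cols = _model_frame(cohort, config.univariate_predictors)
    keep = model_cols.notna().all(axis=1) & df["pcr"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d rows with missing model covariates", n_dropped)
    df = df.loc[keep].reset_index(drop=True)
    cohort = Cohort(df)
    model_cols = model_cols.loc[keep].reset_index(drop=True)
    y = df["pcr"].to_numpy(dtype=float)

    report.sections["volumetry_summary"] = _summary_section(cohort, n_dropped)
    report.sections["correlations"] = _correlation_section(df)
    report.sections["univariate"] = _univariate_section(model_cols, y)

    vif_table, retained = _vif_screen(model_cols, config)
    report.sections["vif"] = vif_table
    report.sections["multivariate"] = _multivariate_section(model_cols[retained], y)

    if {"rtv_cm3", "catv_cm3", "tctv_cm3"} <= set(df.columns):
        report.sections["roc_volumes"] = _roc_section(
            {"rtv": df["rtv_cm3"], "catv": df["catv_cm3"], "tctv": df["tctv_cm3"]}, y
        )
    if config.model_assisted:
        report.sections["roc_model_assisted"] = _model_assisted_section(df, y, config)

    if config.subgroups:
        sub = {}
        for column, value in config.subgroups:
            group = cohort.subgroup(column, value)
            gdf = group.df
            if gdf["pcr"].nunique() < 2 or len(gdf) < 10:
                sub[f"{column}={value}"] = {"n": len(gdf), "error": "too few cases/classes"}
                continue
            sub[f"{column}={value}"] = _roc_section(
                {"rtv": gdf["rtv_cm3"], "catv": gdf["catv_cm3"], "tctv": gdf["tctv_cm3"]},
                gdf["pcr"].to_numpy(dtype=float),
            )
        report.sections["subgroups"] = sub
    return report


def _summary_section(cohort: Cohort, n_dropped: int) -> dict:
    df = cohort.df
    out: dict = {
        "n": len(df),
        "n_excluded_missing": n_dropped,
        "n_pcr": cohort.n_pcr,
        "pcr_prevalence_pct": round(100.0 * cohort.n_pcr / len(df), 1),
    }
    if "cN" in df.columns:
        out["n_cn0"] = int((df["cN"] == 0).sum())
        out["cn0_pct"] = round(100.0 * (df["cN"] == 0).mean(), 1)
    stats_rows = []
    for col in ("long_axis_cm", "diameter_cm", "catv_cm3", "rtv_cm3", "compactness",
                "tctv_cm3"):
        if col in df.columns:
            v = df[col].astype(float)
            stats_rows.append(
                {"feature": col, "median": float(v.median()),
                 "min": float(v.min()), "max": float(v.max())}
            )
    out["features"] = stats_rows
    return out


def _correlation_section(df: pd.DataFrame) -> list[dict]:
    pairs = [("catv_cm3", "rtv_cm3"), ("catv_cm3", "compactness"), ("rtv_cm3", "compactness")]
    rows = []
    for a, b in pairs:
        if a not in df.columns or b not in df.columns:
            continue
        row = {"pair": f"{a} vs {b}"}
        for method in ("pearson", "spearman"):
            r, p = correlate(df[a], df[b], method)
            row[f"{method}_r"], row[f"{method}_p"] = r, p
        rows.append(row)
    return rows


def _fit_rows(fit, predictors) -> list[dict]:
    frame = fit.to_frame()
    rows = []
    for name in predictors:
        r = frame.loc[name]
        rows.append(
            {
                "predictor": name,
                "odds_ratio": float(r["odds_ratio"]),
                "ci_lower": float(r["ci_lower"]),
                "ci_upper": float(r["ci_upper"]),
                "p": float(r["p"]),
                "coef": float(r["coef"]),
                "converged": fit.converged,
            }
        )
    return rows


def _univariate_section(model_cols: pd.DataFrame, y: np.ndarray) -> list[dict]:
    rows = []
    for name in model_cols.columns:
        x = model_cols[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows.append({"predictor": name, "error": "constant predictor"})
            continue
        fit = fit_logistic(x[:, None], y, names=[name])
        if not fit.converged:
            rows.append({"predictor": name, "converged": False, "error": fit.diagnostic})
            continue
        rows.extend(_fit_rows(fit, [name]))
        if name == "cn_pos":
            # report the reverse coding too: OR for cN0 vs cN1-2
            r = rows[-1]
            rows.append(
                {
                    "predictor": "cn_neg (cN0 vs cN1-2)",
                    "odds_ratio": 1.0 / r["odds_ratio"],
                    "ci_lower": 1.0 / r["ci_upper"],
                    "ci_upper": 1.0 / r["ci_lower"],
                    "p": r["p"],
                    "coef": -r["coef"],
                    "converged": True,
                }
            )
    return rows


def _vif_screen(model_cols: pd.DataFrame, config: AnalysisConfig):
    names = [n for n in model_cols.columns if model_cols[n].std() > 0]
    if len(names) < 2:
        return [], names
    table = vif(model_cols[names].to_numpy(dtype=float), names)
    flagged_volumes = [
        v for v in VOLUME_PREDICTORS if v in table.index and table.loc[v, "flag"] != "ok"
    ]
    retained = list(names)
    dropped = None
    if len(flagged_volumes) >= 2:
        dropped = config.vif_drop
        retained = [n for n in names if n != dropped]
        logger.info("VIF screen: dropping %s (volume measures collinear)", dropped)
        table2 = vif(model_cols[retained].to_numpy(dtype=float), retained)
    else:
        table2 = None
    rows = [
        {"predictor": n, "vif": float(table.loc[n, "vif"]), "flag": table.loc[n, "flag"],
         "dropped": n == dropped}
        for n in names
    ]
    if table2 is not None:
        for n in retained:
            rows.append(
                {"predictor": f"{n} (after drop)", "vif": float(table2.loc[n, "vif"]),
                 "flag": table2.loc[n, "flag"], "dropped": False}
            )
    return rows, retained


def _multivariate_section(model_cols: pd.DataFrame, y: np.ndarray) -> list[dict]:
    names = [n for n in model_cols.columns if model_cols[n].std() > 0]
    if not names:
        return []
    fit = fit_logistic(model_cols[names].to_numpy(dtype=float), y, names=names)
    if not fit.converged:
        return [{"converged": False, "error": fit.diagnostic}]
    return _fit_rows(fit, names)


def _single_auc_ci(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """AUC with a Wald 95% CI from the DeLong single-curve variance."""
    from .stats import _placements

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v10, v01, auc = _placements(pos, neg)
    var = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    half = 1.959963984540054 * np.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def _roc_section(score_map: dict, y: np.ndarray) -> dict:
    rows = []
    oriented = {}
    for name, scores in score_map.items():
        scores = np.asarray(scores, dtype=float)
        curve = roc(scores, y, orientation="auto")
        use = -scores if curve.flipped else scores
        oriented[name] = scores
        auc, lo, hi = _single_auc_ci(use, y)
        rows.append(
            {"score": name, "auc": float(curve.auc), "ci_lower": lo, "ci_upper": hi,
             "orientation": "reversed" if curve.flipped else "as_is"}
        )
    comparisons = []
    names = list(score_map.keys())
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            cmp_ = delong_compare(oriented[names[i]], oriented[names[j]], y)
            comparisons.append(
                {
                    "pair": f"{names[i]} vs {names[j]}",
                    "auc_a": cmp_.auc_a,
                    "auc_b": cmp_.auc_b,
                    "auc_difference": cmp_.auc_difference,
                    "z": cmp_.z,
                    "p": cmp_.p,
                }
            )
    return {"auc": rows, "pairwise": comparisons}


def _model_assisted_section(df: pd.DataFrame, y: np.ndarray, config: AnalysisConfig) -> dict:
    needed = {"rtv_cm3", "catv_cm3", "tctv_cm3", "eqd2_gy", "cn_pos"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"model-assisted ROC stage needs columns {sorted(missing)}"
        )
    coefs = config.trp_coefficients
    catv = df["catv_cm3"].to_numpy(dtype=float)
    volumes = {
        "trp_catv": catv,
        "trp_rtv": normalize_to_reference_median(df["rtv_cm3"].to_numpy(dtype=float), catv),
        "trp_tctv": normalize_to_reference_median(df["tctv_cm3"].to_numpy(dtype=float), catv),
    }
    eqd2_gy = df["eqd2_gy"].to_numpy(dtype=float)
    cn = df["cn_pos"].to_numpy(dtype=float)
    scores = {name: trp(coefs, eqd2_gy, vol, cn) for name, vol in volumes.items()}
    return _roc_section(scores, y)


# ----------------------------------------------------------------- manifest


def write_manifest(config: AnalysisConfig, path: str | Path, **extra) -> dict:
    """Machine-readable run manifest: config hash, seed, package versions."""
    import scipy

    import tumorvol

    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "tumorvol": tumorvol.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
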