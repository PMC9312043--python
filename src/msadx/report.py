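"""Cohort characterisation and end-to-end pipeline orchestration.

The cohort summary mirrors a standard clinical characteristics table: graded
and quantitative items are described as mean +/- SD and compared between
subtypes with a Kruskal-Wallis rank test; binary and categorical items are
described as counts (percentage) and compared with a chi-square test, followed
by an adjusted-residual analysis flagging which cells drive a significant
result (|r| > 1.96 at alpha = 0.05, only when the omnibus test is itself
significant). p-values are reported to three decimals, "<0.001" below that.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as sps
import yaml

from . import __version__
from .encoding import build_codebook, encode_cohort, fit_normalization
from .evaluation import double_cross_validate, heldout_probability_table, ovr_mean_auc
from .importance import assign_components, feature_importance, important_features
from .pwl import PWLConfig, forward, train
from .registry import (
    LABEL_COLUMN,
    SUBTYPES,
    Cohort,
    exclude_incomplete,
    form_schema,
    modelling_items,
)
from .synthcohort import CohortSpec, default_profiles, generate_cohort

__all__ = ["kruskal_wallis", "chi2_with_residuals", "summarize_cohort",
           "run_pipeline", "format_p"]

logger = logging.getLogger("msadx")


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate input (every value identical across all groups) returns
    H = 0, p = 1 instead of erroring.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def chi2_with_residuals(table: np.ndarray, alpha: float = 0.05):
    """Pearson chi-square with adjusted residuals and cell flags.

    The adjusted residual of cell (i, j) is
    (O - E) / sqrt(E (1 - row_i/N) (1 - col_j/N)); a cell is flagged "larger"
    (resp. "smaller") when its residual exceeds +/-1.96 AND the omnibus test
    is significant at ``alpha``. Returns (chi2, df, p, residuals, flags).
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or (O < 0).any():
        raise ValueError("table must be a non-negative r x c matrix")
    if (O.sum(axis=1) == 0).any() or (O.sum(axis=0) == 0).any():
        raise ValueError("table has an all-zero row or column")
    chi2, p, df, E = sps.chi2_contingency(O, correction=False)
    if (E == 0).any():
        raise ValueError("expected cell count of zero")
    N = O.sum()
    row = O.sum(axis=1, keepdims=True) / N
    col = O.sum(axis=0, keepdims=True) / N
    resid = (O - E) / np.sqrt(E * (1 - row) * (1 - col))
    flags = np.full(O.shape, "", dtype=object)
    if p < alpha:
        flags[resid > 1.96] = "larger"
        flags[resid < -1.96] = "smaller"
    return float(chi2), int(df), float(p), resid, flags


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _crosstab(series: pd.Series, labels: pd.Series, levels) -> np.ndarray:
    tab = np.zeros((len(levels), len(SUBTYPES)), dtype=int)
    for j, sub in enumerate(SUBTYPES):
        vals = series[labels == sub].dropna()
        for i, lv in enumerate(levels):
            tab[i, j] = int((vals == lv).sum())
    return tab


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Characteristics-by-subtype table over all form items.

    One row per item (binary, ordinal, quantitative) or per item level
    (categorical); columns hold the per-subtype descriptive cell, the test
    p-value and any residual flags. Deterministic; single-subtype cohorts get
    descriptives with tests skipped.
    """
    df = cohort.df
    labels = df[LABEL_COLUMN]
    present = [s for s in SUBTYPES if (labels == s).any()]
    multi = len(present) >= 2
    rows = []
    for item in form_schema():
        if item.is_label or item.kind == "T" or item.item_id not in df.columns:
            continue
        col = df[item.item_id]
        if item.kind in ("O", "Q"):
            cells = {}
            for sub in SUBTYPES:
                v = col[labels == sub].dropna().astype(float)
                cells[sub] = (f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
                              if len(v) else "-")
            if multi:
                groups = [col[labels == s].dropna().to_numpy(dtype=float)
                          for s in present]
                _, p = kruskal_wallis(groups)
                ptxt = format_p(p)
            else:
                ptxt = "n/a (single subtype)"
            rows.append({"item": item.item_id, "level": "", "test": "kruskal",
                         **cells, "p": ptxt,
                         **{f"flag_{s}": "" for s in SUBTYPES}})
        else:  # B or C -> counts (%) + chi-square with residual flags
            levels = list(item.levels)
            tab = _crosstab(col, labels, levels)
            keep = tab.sum(axis=1) > 0
            tab_t = tab[keep]
            ptxt, flags = "n/a (single subtype)", None
            if multi and tab_t.shape[0] >= 2:
                sub_cols = [j for j, s in enumerate(SUBTYPES) if s in present]
                try:
                    _, _, p, _, fl = chi2_with_residuals(tab_t[:, sub_cols])
                    ptxt = format_p(p)
                    flags = np.full(tab.shape, "", dtype=object)
                    flags[np.ix_(keep, sub_cols)] = fl
                except ValueError:
                    ptxt = "n/a"
            level_rows = [0] if item.kind == "B" else range(len(levels))
            for i in level_rows:
                denom = tab.sum(axis=0)
                cells = {}
                for j, sub in enumerate(SUBTYPES):
                    pct = 100.0 * tab[i, j] / denom[j] if denom[j] else 0.0
                    cells[sub] = f"{tab[i, j]} ({pct:.1f})"
                rows.append({
                    "item": item.item_id,
                    "level": ("presence" if item.kind == "B" else str(levels[i])),
                    "test": "chi2", **cells, "p": ptxt,
                    **{f"flag_{s}": (flags[i, j] if flags is not None else "")
                       for j, s in enumerate(SUBTYPES)},
                })
    return pd.DataFrame(rows)


DEFAULT_PIPELINE_CONFIG = {
    "input_csv": None,           # path; None -> simulate
    "n": {"SND": 851, "SDS": 359, "OPCA": 2010},
    "missingness_rate": 157.0 / 3377.0,
    "variant": "b",
    "seed": 0,
    "model": {},                 # PWLConfig field overrides
    "k_outer": 10,
    "k_inner": 5,
    "run_dcv": True,
    "n_heldout_per_class": 10,
    "importance_threshold": 0.30,
    "importance_fraction": 0.10,
}


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir) -> Path:
    """Execute the full analysis: simulate/load -> exclude -> encode -> DCV ->
    held-out probability table -> per-subtype importance -> cohort summary.

    ``config`` is a dict (or path to a YAML file) overriding
    ``DEFAULT_PIPELINE_CONFIG``. All artifacts, a manifest (config hash, seed,
    version) and a log are written under ``out_dir``. Stage failures abort
    with the stage name; artifacts already written are retained.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        seed = int(cfg["seed"])
        stage = "simulate/load"
        if cfg["input_csv"]:
            cohort = Cohort.read_csv(cfg["input_csv"])
        else:
            cohort = generate_cohort(CohortSpec(
                n=dict(cfg["n"]), missingness_rate=float(cfg["missingness_rate"]),
                seed=seed))
            cohort.to_csv(out / "cohort.csv")
        logger.info("cohort: %d cases (%s)", len(cohort), cohort.provenance)

        stage = "exclude"
        kept, n_excl = exclude_incomplete(cohort)
        logger.info("complete-case filter: kept %d, excluded %d",
                    len(kept), n_excl)

        stage = "summarize"
        summary = summarize_cohort(kept)
        summary.to_csv(out / "cohort_characteristics.csv", index=False)

        stage = "encode"
        codebook = build_codebook(cfg["variant"])
        norm = fit_normalization(kept, codebook)
        matrix = encode_cohort(kept, codebook, norm)
        matrix.to_frame().to_csv(out / f"design_{cfg['variant']}.csv",
                                 index=False)

        model_cfg = PWLConfig(**{"seed": seed, **cfg["model"]})

        if cfg.get("run_dcv", True):
            stage = "double-cross-validation"
            report = double_cross_validate(matrix, [model_cfg],
                                           k_outer=int(cfg["k_outer"]),
                                           k_inner=int(cfg["k_inner"]),
                                           seed=seed)
            (out / "dcv.json").write_text(
                json.dumps(report.to_dict(), indent=2))
            logger.info("%s", report)

        stage = "heldout"
        table, _ = heldout_probability_table(
            matrix, model_cfg, n_per_class=int(cfg["n_heldout_per_class"]),
            seed=seed)
        table.to_csv(out / "heldout_probabilities.csv", index=False)

        stage = "importance"
        params = train(matrix, model_cfg)
        pred = forward(params, matrix.values)
        groupings = {}
        for c, sub in enumerate(SUBTYPES):
            imp = feature_importance(pred.weights[:, c, :], matrix.values,
                                     codebook,
                                     fraction=float(cfg["importance_fraction"]))
            top = important_features(imp, float(cfg["importance_threshold"]))
            top = assign_components(top, codebook)
            top.to_csv(out / f"importance_{sub}.csv", index=False)
            groupings[sub] = [
                {"feature": r["feature"], "component": r["component"],
                 "sign": r["sign"], "score": round(float(r["score"]), 3)}
                for _, r in top.iterrows()]
        (out / "components.json").write_text(json.dumps(groupings, indent=2))

        stage = "manifest"
        manifest = {"config": cfg, "config_hash": _config_hash(cfg),
                    "seed": seed, "msadx_version": __version__,
                    "n_cases": len(cohort), "n_modelled": len(kept),
                    "n_excluded": n_excl}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
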