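"""End-to-end orchestration: derived indices, PGLS plan, optional imputation.

The analysis asks three questions about the Darwin-Bateman cascade: does
the degree of anisogamy (gamete size or gametic investment bias) predict
the sex difference in selection intensity; does the sex difference in
selection predict parental care bias; and does it predict sexual size
dimorphism.  The plan therefore pairs each selection effect size (lnCVR of
reproductive success, lnCVR of mating success, Hedges' d of the Bateman
gradient) with each life-history index in bivariate PGLS models, plus
multi-predictor models with all three predictor classes at once.

Two dataset modes are supported, mirroring how analyses with missing data
are usually reported: ``original`` (casewise deletion per model) and
``complete`` (phylogenetic multiple imputation of the continuous indices,
m completed datasets analysed separately, parameters pooled to mean ± SD).
Care scores are never imputed, and models involving care use only species
that exhibit some level of care.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trait_indices as ti
from .imputation import draw_imputations, fit_phylo_mvn, impute_moments, pool_fits
from .pgls import InsufficientDataError, PGLSFit, pgls
from .phylogeny import Phylogeny

__all__ = [
    "AnalysisPlan",
    "PipelineReport",
    "SELECTION_INDICES",
    "IMPUTABLE_COLUMNS",
    "default_plan",
    "derive_indices",
    "run_plan",
]

SELECTION_INDICES = ("delta_I", "delta_I_s", "delta_beta_ss")
GAMETIC_INDICES = ("gamete_size_bias", "gametic_investment_bias")

#: Continuous derived columns eligible for imputation; care is excluded.
IMPUTABLE_COLUMNS = list(SELECTION_INDICES) + list(GAMETIC_INDICES) + ["ssd"]

#: Raw life-history columns imputed on the natural-log scale.
RAW_LOG_COLUMNS = [
    "male_mass_g",
    "female_mass_g",
    "male_gamete_size",
    "female_gamete_mass_g",
    "testis_mass_g",
    "clutch_size",
]


@dataclass
class AnalysisPlan:
    """The set of PGLS models to fit and the dataset modes to fit them in."""

    models: list[str]
    dataset_modes: tuple[str, ...] = ("original",)

    def __post_init__(self) -> None:
        for mode in self.dataset_modes:
            if mode not in ("original", "complete"):
                raise ValueError(f"unknown dataset mode {mode!r}")

    def validate_against(self, table: pd.DataFrame) -> None:
        from .pgls import _parse_model

        for model in self.models:
            resp, preds = _parse_model(model)
            missing = [v for v in [resp] + preds if v not in table.columns]
            if missing:
                raise KeyError(f"model {model!r} references absent columns {missing}")


def default_plan(modes: tuple[str, ...] = ("original",)) -> AnalysisPlan:
    """Bivariate and multi-predictor models of the standard analysis.

    Bivariate: each selection index against each gametic bias; care score
    against each index; SSD against each index.  Multi-predictor: each
    selection index against one gametic bias + SSD + care score (six
    models).
    """
    models: list[str] = []
    for idx in SELECTION_INDICES:
        for gam in GAMETIC_INDICES:
            models.append(f"{idx} ~ {gam}")
    for idx in SELECTION_INDICES:
        models.append(f"care_score ~ {idx}")
    for idx in SELECTION_INDICES:
        models.append(f"ssd ~ {idx}")
    for idx in SELECTION_INDICES:
        for gam in GAMETIC_INDICES:
            models.append(f"{idx} ~ {gam} + ssd + care_score")
    return AnalysisPlan(models=models, dataset_modes=modes)


def _row_value(row: pd.Series, col: str) -> float | None:
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def derive_indices(
    raw: pd.DataFrame, prefer_precomputed: bool = True
) -> pd.DataFrame:
    """One row per species with every derived analysis variable.

    Selection effect sizes are passed through when supplied pre-computed
    (``prefer_precomputed``, the default, matches taking them from an
    existing compilation) and otherwise computed from the per-sex success
    summaries.  A missing input propagates to every index depending on it;
    other indices for the species are still computed.
    """
    out = pd.DataFrame(index=raw.index)

    def from_summaries(prefix: str, fn) -> list[float]:
        cols = [f"{prefix}_{s}_{x}" for x in ("m", "f") for s in ("mean", "sd", "n")]
        vals = []
        for _, row in raw.iterrows():
            args = [_row_value(row, f"{prefix}_{s}_{x}")
                    for x in ("m", "f") for s in ("mean", "sd", "n")]
            if any(a is None for a in args):
                vals.append(np.nan)
                continue
            mm, sm, nm, mf, sf, nf = args
            vals.append(fn(mm, sm, int(nm), mf, sf, int(nf)))
        return vals

    for col, prefix, fn in (
        ("delta_I", "rs", ti.ln_cvr),
        ("delta_I_s", "ms", ti.ln_cvr),
        ("delta_beta_ss", "bss", ti.hedges_d),
    ):
        if prefer_precomputed and col in raw.columns:
            out[col] = pd.to_numeric(raw[col], errors="coerce")
        elif any(c.startswith(prefix + "_") for c in raw.columns):
            out[col] = from_summaries(prefix, fn)
        elif col in raw.columns:
            out[col] = pd.to_numeric(raw[col], errors="coerce")
        else:
            raise KeyError(f"cannot derive {col}: no precomputed column or "
                           f"{prefix}_* summaries in table")

    def per_row(fn, cols):
        vals = []
        for _, row in raw.iterrows():
            args = [_row_value(row, c) for c in cols]
            vals.append(np.nan if any(a is None for a in args) else fn(*args))
        return vals

    for req in ("male_mass_g", "female_mass_g"):
        if req not in raw.columns:
            raise KeyError(f"required column {req!r} missing from raw table")

    out["ssd"] = per_row(lambda m, f: ti.ssd(m, f, dimension="weight"),
                         ["male_mass_g", "female_mass_g"])
    out["gamete_size_bias"] = per_row(
        ti.gamete_size_bias,
        ["male_gamete_size", "male_mass_g", "female_gamete_mass_g", "female_mass_g"],
    )
    out["gametic_investment_bias"] = per_row(
        ti.gametic_investment_bias,
        ["testis_mass_g", "male_mass_g", "female_gamete_mass_g",
         "clutch_size", "female_mass_g"],
    )

    scores, flags = [], []
    for _, row in raw.iterrows():
        has = bool(row["has_care"]) if "has_care" in raw.columns and not pd.isna(row.get("has_care")) else True
        pct = _row_value(row, "percent_male_care")
        if not has or pct is None:
            cs = ti.CareScore(None, False) if not has else ti.CareScore(None, has)
            scores.append(np.nan)
            flags.append(has and pct is not None)
        else:
            cs = ti.care_score(pct, has_care=has)
            scores.append(cs.score if cs.score is not None else np.nan)
            flags.append(cs.has_care)
    out["care_score"] = scores
    out["has_care"] = flags
    if "is_auxiliary" in raw.columns:
        out["is_auxiliary"] = raw["is_auxiliary"].astype(bool)
    return out


@dataclass
class PipelineReport:
    """Model-by-term results plus skip records and the run manifest."""

    table: pd.DataFrame
    skipped: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.table.to_csv(os.path.join(outdir, "report.csv"), index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        if self.skipped:
            pd.DataFrame(self.skipped).to_csv(
                os.path.join(outdir, "skipped.csv"), index=False
            )


_BASE_COLS = ["model", "dataset_mode", "term", "estimate", "se", "t", "p",
              "lambda_hat", "adj_r2", "n"]


def _model_uses_care(model: str) -> bool:
    return "care_score" in model


def _restrict(table: pd.DataFrame, model: str) -> pd.DataFrame:
    sub = table
    if "is_auxiliary" in sub.columns:
        sub = sub.loc[~sub["is_auxiliary"].astype(bool)]
    if _model_uses_care(model) and "has_care" in sub.columns:
        sub = sub.loc[sub["has_care"].astype(bool)]
    return sub


def _fit_rows(fit: PGLSFit, model: str, mode: str) -> list[dict]:
    rows = []
    for j, term in enumerate(fit.terms):
        rows.append(
            {
                "model": model,
                "dataset_mode": mode,
                "term": term,
                "estimate": fit.params[j],
                "se": fit.bse[j],
                "t": fit.tvalues[j],
                "p": fit.pvalues[j],
                "lambda_hat": fit.lambda_hat,
                "adj_r2": fit.adj_r2,
                "n": fit.n_used,
            }
        )
    return rows


def _pooled_rows(pooled, model: str) -> list[dict]:
    rows = []
    for _, rec in pooled.table.iterrows():
        rows.append(
            {
                "model": model,
                "dataset_mode": "complete",
                "term": rec["term"],
                "estimate": rec["estimate_mean"],
                "estimate_sd": rec["estimate_sd"],
                "se": rec["se_mean"],
                "se_sd": rec["se_sd"],
                "t": rec["t_mean"],
                "t_sd": rec["t_sd"],
                "p": rec["p_mean"],
                "p_sd": rec["p_sd"],
                "lambda_hat": rec["lambda_hat_mean"],
                "lambda_hat_sd": rec["lambda_hat_sd"],
                "adj_r2": rec["adj_r2_mean"],
                "adj_r2_sd": rec["adj_r2_sd"],
                "n": rec["n_used_mean"],
                "n_sd": rec["n_used_sd"],
            }
        )
    return rows


def _impute_block(raw: pd.DataFrame | None, derived: pd.DataFrame):
    """Variables entering the joint imputation model, on modelling scale.

    With the raw table available the model covers the log-scale
    life-history traits plus the three selection effect sizes — imputing
    the measured quantities and re-deriving indices afterwards keeps the
    cross-trait covariances estimable from every pairwise overlap, instead
    of from the much sparser joint support of composite indices.  Without a
    raw table the continuous derived indices are imputed directly.
    """
    if raw is None:
        cols = [c for c in IMPUTABLE_COLUMNS if c in derived.columns]
        return derived[cols], "derived", cols
    block = pd.DataFrame(index=raw.index)
    log_cols = [c for c in RAW_LOG_COLUMNS if c in raw.columns]
    for c in log_cols:
        block[f"ln_{c}"] = np.log(pd.to_numeric(raw[c], errors="coerce"))
    for c in SELECTION_INDICES:
        block[c] = derived[c]
    return block, "raw", log_cols


def _rebuild_derived(
    completed_block: pd.DataFrame, raw: pd.DataFrame, log_cols: list[str]
) -> pd.DataFrame:
    """Re-derive the analysis table from one completed raw-scale table."""
    filled_raw = raw.copy()
    for c in log_cols:
        filled_raw[c] = np.exp(completed_block[f"ln_{c}"])
    for c in SELECTION_INDICES:
        filled_raw[c] = completed_block[c]
    return derive_indices(filled_raw, prefer_precomputed=True)


def run_plan(
    derived: pd.DataFrame,
    tree: Phylogeny,
    plan: AnalysisPlan | None = None,
    *,
    raw: pd.DataFrame | None = None,
    m: int = 10,
    seed: int = 0,
    impute_lambda: float | None = None,
    graft: dict[str, tuple[str, float]] | None = None,
) -> PipelineReport:
    """Fit every planned model in every requested dataset mode.

    ``original`` fits each model on the rows complete for its variables.
    ``complete`` first fits the joint Brownian+lambda model — to the
    log-scale raw traits plus selection effect sizes when ``raw`` is
    supplied, otherwise to the continuous derived indices — draws ``m``
    completed tables, re-derives the analysis variables, fits each model on
    every completed table, and pools parameters to mean ± SD.  Auxiliary
    species participate in the imputation model but not in the fits.  A
    model with too few usable species produces a skip record, never a
    crash; every plan entry yields exactly one outcome.
    """
    if plan is None:
        plan = default_plan()
    plan.validate_against(derived)
    if graft:
        for new_tip, (sister, frac) in graft.items():
            tree = tree.graft_species(new_tip, sister, stem_fraction=frac)
    missing_species = [s for s in derived.index if s not in set(tree.tip_labels)]
    if missing_species:
        raise KeyError(
            f"species absent from tree: {missing_species}; graft them "
            "(the `graft` option, mirroring manual tree additions) or drop them"
        )

    rows: list[dict] = []
    skipped: list[dict] = []
    manifest: dict = {"seed": seed, "m": m, "models": list(plan.models),
                      "modes": list(plan.dataset_modes), "lambda_by_model": {}}

    if "original" in plan.dataset_modes:
        for model in plan.models:
            sub = _restrict(derived, model)
            try:
                fit = pgls(model, sub, tree)
            except InsufficientDataError as exc:
                skipped.append({"model": model, "dataset_mode": "original",
                                "reason": str(exc)})
                continue
            rows.extend(_fit_rows(fit, model, "original"))
            manifest["lambda_by_model"][f"original::{model}"] = fit.lambda_hat

    if "complete" in plan.dataset_modes:
        block, block_kind, log_cols = _impute_block(raw, derived)
        n_missing = int(block.isna().to_numpy().sum())
        if n_missing == 0:
            completed = [derived]
            manifest["imputation"] = {"n_missing_cells": 0, "m_effective": 1}
        else:
            params = fit_phylo_mvn(block, tree, lam=impute_lambda)
            moments = impute_moments(block, tree, params)
            imps = draw_imputations(moments, block, m=m, seed=seed)
            completed = []
            for tab in imps.tables:
                if block_kind == "raw":
                    completed.append(_rebuild_derived(tab, raw, log_cols))
                else:
                    full = derived.copy()
                    full[list(block.columns)] = tab[list(block.columns)]
                    completed.append(full)
            manifest["imputation"] = {
                "block": block_kind,
                "variables": list(block.columns),
                "n_missing_cells": n_missing,
                "m_effective": m,
                "lambda_hat": params.lam,
                "seeds": imps.seeds,
            }
        for model in plan.models:
            fits = []
            fail = None
            for tab in completed:
                sub = _restrict(tab, model)
                try:
                    fits.append(pgls(model, sub, tree))
                except InsufficientDataError as exc:
                    fail = str(exc)
                    break
            if fail is not None:
                skipped.append({"model": model, "dataset_mode": "complete",
                                "reason": fail})
                continue
            if len(fits) == 1:  # no missing data: single fit, zero spread
                rec = _fit_rows(fits[0], model, "complete")
                for r in rec:
                    for c in ("estimate", "se", "t", "p", "lambda_hat",
                              "adj_r2", "n"):
                        r[c + "_sd"] = 0.0
                rows.extend(rec)
            else:
                rows.extend(_pooled_rows(pool_fits(fits), model))

    table = pd.DataFrame(rows)
    if not table.empty:
        ordered = [c for c in _BASE_COLS if c in table.columns]
        extra = [c for c in table.columns if c not in ordered]
        table = table[ordered + extra]
    return PipelineReport(table=table, skipped=skipped, manifest=manifest)
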