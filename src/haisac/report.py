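"""Assembly of the full validation report for a scored cohort.

Mirrors the published report surface of screening-test validation studies:
a demographics/score comparison block (ANOVA + chi-square), a reliability
and EFA block on the five-item battery, a criterion-validity correlation
block (total score and factor scores against comparator scales), and the
discrimination grid (ROC per diagnostic contrast × test, with paired DeLong
comparisons of the instrument against every comparator).
"""

from __future__ import annotations

import hashlib
import json
from typing import Sequence

import numpy as np
import pandas as pd

from . import groupstats, psychometrics, roc

__all__ = ["build_validation_report", "render_text", "DEFAULT_CONTRASTS", "DEFAULT_TESTS"]

DEFAULT_CONTRASTS = (("CU", "MCI"), ("MCI", "DAT"), ("CU", "DAT"))
#: test name → cohort column
DEFAULT_TESTS = {
    "haisac": "haisac_total",
    "haisac3": "haisac3",
    "haisaci": "haisaci",
    "casi": "casi",
    "mmse": "mmse",
    "moca": "moca",
}

BATTERY_ITEMS = ("cnocd", "ml", "rfo", "cd", "fd")
_SEVERITY_ORDER = {"CU": 0, "MCI": 1, "DAT": 2}
GROUP_COMPARISON_VARIABLES = (
    "age", "education_years", "cdr_sb", "npi_sb", "iadl",
    "casi", "mmse", "moca", "haisac_total", "haisac3", "haisaci",
)
COMPARATOR_SCALES = ("mmse", "casi", "moca", "cdr_sb", "npi_sb", "iadl")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _roc_block(result: roc.RocResult) -> dict:
    return {
        "auc": result.auc,
        "ci95": [result.ci_lower, result.ci_upper],
        "optimal_cutoff": result.optimal_cutoff_label,
        "sensitivity": result.optimal_sensitivity,
        "specificity": result.optimal_specificity,
        "youden_j": result.youden_j,
        "n_cases": result.n_cases,
        "n_controls": result.n_controls,
    }


def build_validation_report(
    cohort: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
    tests: dict[str, str] | None = None,
) -> dict:
    """Run the whole validation pipeline on a cohort table.

    Blocks whose input columns are missing are marked skipped with a reason
    rather than failing the run.  The report is a JSON-serializable dict;
    metadata records the cohort digest and seed (when the frame carries one)
    so that identical inputs give byte-identical reports.
    """
    if tests is None:
        tests = dict(DEFAULT_TESTS)
    report: dict = {}
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(cohort, index=False).values.tobytes()
    ).hexdigest()
    report["metadata"] = {
        "n_subjects": int(len(cohort)),
        "groups": {g: int(c) for g, c in cohort["group"].value_counts().items()},
        "cohort_digest": digest,
        "seed": cohort.attrs.get("seed"),
    }

    # --- reliability + EFA on the five-item battery
    battery_cols = [c for c in BATTERY_ITEMS if c in cohort.columns]
    factor_cols: dict[str, np.ndarray] = {}
    if len(battery_cols) == len(BATTERY_ITEMS):
        battery = cohort[list(BATTERY_ITEMS)]
        rel = psychometrics.reliability(battery)
        report["reliability"] = {
            "alpha": rel.alpha,
            "kmo_overall": rel.kmo_overall,
            "kmo_per_item": dict(zip(rel.items, rel.kmo_per_item)),
            "bartlett_chi2": rel.bartlett_chi2,
            "bartlett_df": rel.bartlett_df,
            "bartlett_p": rel.bartlett_p,
        }
        efa_res = psychometrics.efa(battery)
        report["efa"] = {
            "n_factors": efa_res.n_factors,
            "eigenvalues": efa_res.eigenvalues,
            "pattern_loadings": {
                item: dict(zip(efa_res.factor_names, row))
                for item, row in zip(efa_res.items, efa_res.pattern_loadings)
            },
            "factor_correlation": efa_res.factor_correlation,
            "variance_explained_pct": efa_res.variance_explained,
            "communalities": dict(zip(efa_res.items, efa_res.communalities)),
            "heywood": efa_res.heywood,
        }
        scores = psychometrics.factor_scores(battery, efa_res.pattern_loadings)
        # name factors by content: the factor loading CNOCD hardest is the
        # semantic-memory/contextual-binding one, the other the informant one
        cn = list(efa_res.items).index("cnocd")
        smcb_col = int(np.argmax(np.abs(efa_res.pattern_loadings[cn])))
        factor_cols["smcb"] = scores[:, smcb_col]
        if efa_res.n_factors > 1:
            inf_col = 1 - smcb_col if efa_res.n_factors == 2 else int(
                np.argmax(np.abs(efa_res.pattern_loadings[list(efa_res.items).index("cd")]))
            )
            factor_cols["inf"] = scores[:, inf_col]
    else:
        missing = sorted(set(BATTERY_ITEMS) - set(battery_cols))
        reason = f"missing item columns: {missing}"
        report["reliability"] = {"skipped": reason}
        report["efa"] = {"skipped": reason}

    # --- criterion validity correlations
    corr_frame = cohort.copy()
    for name, col in factor_cols.items():
        corr_frame[name] = col
    predictors = [c for c in ("haisac_total", "smcb", "inf") if c in corr_frame.columns]
    comparators = [c for c in COMPARATOR_SCALES if c in corr_frame.columns]
    if predictors and comparators:
        pairs = [(p, c) for p in predictors for c in comparators]
        rep = groupstats.pearson_correlations(corr_frame, variable_pairs=pairs)
        pos = {v: i for i, v in enumerate(rep.variables)}
        report["correlations"] = {
            p: {
                c: {
                    "r": rep.r_matrix[pos[p], pos[c]],
                    "p": rep.p_values[pos[p], pos[c]],
                    "strength": rep.strength_labels[(p, c)],
                }
                for c in comparators
            }
            for p in predictors
        }
    else:
        report["correlations"] = {"skipped": "no predictor/comparator columns available"}

    # --- group comparisons
    comparisons: dict = {}
    for var in GROUP_COMPARISON_VARIABLES:
        if var not in cohort.columns:
            continue
        res = groupstats.anova_oneway(cohort[var].to_numpy(), cohort["group"].to_numpy())
        comparisons[var] = {
            "f": res.f_statistic,
            "df": [res.df_between, res.df_within],
            "p": res.p_value,
            "pairwise": {
                f"{a}:{b}": {"t": d["t"], "p": d["p"], "significant": d["significant"]}
                for (a, b), d in res.pairwise.items()
            },
        }
    if "sex" in cohort.columns:
        table = pd.crosstab(cohort["group"], cohort["sex"])
        chi2, df, p = groupstats.chi_square_independence(table.to_numpy())
        comparisons["sex"] = {"chi2": chi2, "df": df, "p": p}
    report["group_comparisons"] = comparisons or {"skipped": "no comparable columns"}

    # --- discrimination grid
    grid: dict = {}
    for lo_grp, hi_grp in contrasts:
        if _SEVERITY_ORDER.get(hi_grp, 99) < _SEVERITY_ORDER.get(lo_grp, -1):
            lo_grp, hi_grp = hi_grp, lo_grp  # cases are always the more impaired arm
        key = f"{lo_grp}:{hi_grp}"
        block: dict = {}
        case_mask = (cohort["group"] == hi_grp).to_numpy()
        ctrl_mask = (cohort["group"] == lo_grp).to_numpy()
        if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
            grid[key] = {"skipped": f"contrast {key} has an empty arm"}
            continue
        sub_mask = case_mask | ctrl_mask
        for test, col in tests.items():
            if col not in cohort.columns:
                block[test] = {"skipped": f"missing column {col!r}"}
                continue
            scores = cohort[col].to_numpy(dtype=float)
            block[test] = _roc_block(roc.empirical_roc(scores[case_mask], scores[ctrl_mask]))
        anchor = "haisac"
        if anchor in tests and tests[anchor] in cohort.columns:
            anchor_scores = cohort[tests[anchor]].to_numpy(dtype=float)[sub_mask]
            labels = case_mask[sub_mask]
            for test, col in tests.items():
                if test == anchor or col not in cohort.columns:
                    continue
                other = cohort[col].to_numpy(dtype=float)[sub_mask]
                d = roc.delong_paired_test(anchor_scores, other, labels)
                block[test]["vs_haisac"] = {
                    "auc_diff": d.auc_1 - d.auc_2,
                    "chi2": d.statistic,
                    "p": d.p_value,
                }
        grid[key] = block
    report["discrimination"] = grid
    return _jsonable(report)


def render_text(report: dict) -> str:
    """Aligned-text rendering of a validation report (human surface)."""
    lines: list[str] = []
    meta = report.get("metadata", {})
    lines.append("HAI-SAC validation report")
    lines.append(f"  subjects: {meta.get('n_subjects')}  groups: {meta.get('groups')}")
    lines.append(f"  cohort digest: {str(meta.get('cohort_digest'))[:16]}…  seed: {meta.get('seed')}")
    rel = report.get("reliability", {})
    if "skipped" in rel:
        lines.append(f"reliability: skipped ({rel['skipped']})")
    else:
        lines.append(
            f"reliability: alpha={rel['alpha']:.3f}  KMO={rel['kmo_overall']:.3f}  "
            f"Bartlett chi2({rel['bartlett_df']})={rel['bartlett_chi2']:.2f}, p={rel['bartlett_p']:.3g}"
        )
    efa_block = report.get("efa", {})
    if "skipped" not in efa_block:
        lines.append(
            f"EFA: {efa_block['n_factors']} factors, variance explained "
            + " / ".join(f"{v:.1f}%" for v in efa_block["variance_explained_pct"])
        )
        for item, row in efa_block["pattern_loadings"].items():
            lines.append("  " + f"{item:8s}" + "  ".join(f"{v:+.2f}" for v in row.values()))
    disc = report.get("discrimination", {})
    for contrast, block in disc.items():
        lines.append(f"discrimination {contrast}:")
        if "skipped" in block:
            lines.append(f"  skipped ({block['skipped']})")
            continue
        for test, vals in block.items():
            if "skipped" in vals:
                lines.append(f"  {test:8s} skipped ({vals['skipped']})")
                continue
            extra = ""
            if "vs_haisac" in vals:
                extra = f"  vs HAI-SAC p={vals['vs_haisac']['p']:.3g}"
            lines.append(
                f"  {test:8s} AUC={vals['auc']:.2f} "
                f"[{vals['ci95'][0]:.2f}, {vals['ci95'][1]:.2f}] "
                f"cutoff {vals['optimal_cutoff']:>6s} "
                f"sens={vals['sensitivity']:.2f} spec={vals['specificity']:.2f}{extra}"
            )
    return "\n".join(lines)


def dump_json(report: dict) -> str:
    """Deterministic JSON rendering (sorted keys, fixed float formatting)."""
    return json.dumps(report, indent=2, sort_keys=True)
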