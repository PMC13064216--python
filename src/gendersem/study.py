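"""Full-study orchestration: simulate -> preprocess -> impute -> fit -> pool.

A study run fits, per outcome (migraine, stroke), the joint SEM in which
latent gender is measured by ten gender-related indicators, regressed on
binary sex, and enters the outcome equation next to sex, sexual orientation,
partner, age (in decades), the three before-outcome risk-factor flags and
(optionally) immigration history.  Analyses repeat over the m completed
datasets from chained-equation imputation and are pooled with Rubin's rules;
coefficients involving the latent are reported on the sex-anchored 0/1
gender scale.  Variants: unweighted main analysis, weighted analysis
(weighted covariance input), age-group-stratified fits, and a sensitivity
model that removes the sex->gender link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import dag, impute, preprocess, sem, simulate
from .dag import SemSpecification

__all__ = [
    "StudyConfig",
    "StudyResults",
    "adapt_spec_to_columns",
    "run_study",
    "describe_population",
    "cumulative_incidence",
]

VARIANTS = ("main", "weighted", "age-stratified", "sensitivity-no-sex-link")

#: graph-node -> analysis-table column translation; risk factors are
#: outcome-specific before-flags.
_RENAME = {"sex": "sex_binary", "age": "age10"}
_RISK = {"smoking": "smoke", "hypertension": "hypertension", "diabetes": "diabetes"}


@dataclass
class StudyConfig:
    synthetic: simulate.SyntheticConfig = field(
        default_factory=simulate.SyntheticConfig)
    panel_path: str | None = None
    outcomes: tuple[str, ...] = ("migraine", "stroke")
    variants: tuple[str, ...] = ("main",)
    m: int = 20
    mice_iterations: int = 10
    include_immigration: bool = True
    collapse: str = "first_health_wave"
    seed: int = 0

    def validate(self) -> None:
        if not self.variants:
            raise ValueError("select at least one analysis variant")
        bad = set(self.variants) - set(VARIANTS)
        if bad:
            raise ValueError(f"unknown variants: {sorted(bad)}")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class StudyResults:
    results: dict
    descriptives: dict
    exclusion_reports: dict
    provenance: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"results": self.results, "descriptives": self.descriptives,
             "exclusion_reports": self.exclusion_reports,
             "provenance": self.provenance},
            sort_keys=True, indent=1, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    raise TypeError(f"not JSON-serializable: {type(o)}")


def adapt_spec_to_columns(
    spec: SemSpecification, outcome: str,
) -> SemSpecification:
    """Translate a graph-compiled specification to analysis-table columns.

    Keeps the latent (gender) equation plus the single requested outcome
    equation, renames sex/age to their analysis-scale columns, expands the
    immigration category into its two dummies, and maps risk-factor nodes to
    the outcome-specific before-flags.
    """

    def rename(node: str) -> list[str]:
        if node == "immigration":
            return ["imm_indirect", "imm_direct"]
        if node in _RISK:
            return [f"{_RISK[node]}_before_{outcome}"]
        return [_RENAME.get(node, node)]

    structural = []
    for y, preds in spec.structural:
        if y in spec.latents:
            structural.append((y, tuple(p for x in preds for p in rename(x))))
        elif y == outcome:
            new_preds = tuple(p for x in preds for p in rename(x))
            structural.append((f"{outcome}_incident", new_preds))
    ind_regs = [
        (ind, tuple(p for x in covs for p in rename(x)))
        for ind, covs in spec.indicator_regressions
    ]
    exog = []
    for v in spec.exogenous:
        if v in dag.RISK_FACTORS:
            exog.extend(rename(v))
        else:
            exog.extend(rename(v))
    return SemSpecification(
        latents=dict(spec.latents),
        indicator_regressions=ind_regs,
        structural=structural,
        exogenous=tuple(dict.fromkeys(exog)),
        scaling_rule=spec.scaling_rule,
        dropped_edges=list(spec.dropped_edges),
    )


def _drop_sex_link(spec: SemSpecification) -> SemSpecification:
    structural = [(y, p) for y, p in spec.structural if y not in spec.latents]
    return SemSpecification(
        latents=dict(spec.latents),
        indicator_regressions=list(spec.indicator_regressions),
        structural=structural,
        exogenous=spec.exogenous,
        scaling_rule=spec.scaling_rule,
        dropped_edges=list(spec.dropped_edges),
    )


def _fit_one(spec, data, weights=None):
    """Fit, score, and rescale to the sex-anchored 0/1 gender scale."""
    fit = sem.fit_sem(spec, data=data, weights=weights)
    scores = sem.factor_scores(fit, data)
    female = data["sex_binary"].to_numpy() == 1.0
    scores, params = sem.rescale_gender(scores, female, fit.params)
    return fit, scores, params


def _gender_summary(scores, data):
    """Distribution of the rescaled gender score per sex x age-group and
    per sex x immigration: mean, SD, deciles."""
    frame = pd.DataFrame({
        "score": scores.rescaled,
        "sex": data["sex"].to_numpy(),
        "age_group": data["age_group"].to_numpy(),
        "immigration": data["immigration"].to_numpy(),
    })
    out = {}
    for strat in ("age_group", "immigration"):
        rows = {}
        for (sex, grp), chunk in frame.groupby(["sex", strat], sort=True):
            q = np.quantile(chunk["score"], np.arange(0.1, 1.0, 0.1))
            rows[f"{sex}|{grp}"] = {
                "n": int(len(chunk)),
                "mean": float(chunk["score"].mean()),
                "sd": float(chunk["score"].std(ddof=1)),
                "deciles": [float(x) for x in q],
            }
        out[f"by_sex_{strat}"] = rows
    return out


def _average_summaries(summaries: list[dict]) -> dict:
    """Element-wise mean of per-imputation gender-distribution summaries."""
    if len(summaries) == 1:
        return summaries[0]
    out = {}
    for block in summaries[0]:
        out[block] = {}
        for key in summaries[0][block]:
            cells = [s[block][key] for s in summaries]
            out[block][key] = {
                "n": cells[0]["n"],
                "mean": float(np.mean([c["mean"] for c in cells])),
                "sd": float(np.mean([c["sd"] for c in cells])),
                "deciles": list(np.mean([c["deciles"] for c in cells], axis=0)),
            }
    return out


def _pool_block(spec, datasets, weighted: bool):
    fits, scores_list, params_list, summaries = [], [], [], []
    for data in datasets:
        w = data["weight"].to_numpy(dtype=float) if weighted else None
        fit, scores, params = _fit_one(spec, data, weights=w)
        fits.append(fit)
        scores_list.append(scores)
        params_list.append(params)
        summaries.append(_gender_summary(scores, data))
    pooled = impute.pool_rubin(params_list)
    indices = [f.indices.to_dict() for f in fits]
    mean_idx = {
        k: float(np.mean([ix[k] for ix in indices]))
        for k in ("chi2", "df", "rmsea", "srmr", "aic", "loglik")
    }
    return {
        "pooled": pooled.table,
        "fit_indices": indices,
        "fit_indices_mean": mean_idx,
        "converged": all(f.converged for f in fits),
        "gender_summary": _average_summaries(summaries),
    }


def run_study(config: StudyConfig) -> StudyResults:
    """Execute the configured study end to end; deterministic per seed."""
    config.validate()
    provenance: dict = {"seed": config.seed, "stages": []}

    if config.panel_path:
        panel = pd.read_csv(config.panel_path)
        provenance["stages"].append({"stage": "ingest", "path": config.panel_path})
    else:
        syn = config.synthetic
        syn.seed = config.seed
        panel, _truth = simulate.generate_panel(syn)
        if syn.missing_rates:
            panel = simulate.inject_missingness(panel, syn)
        provenance["stages"].append(
            {"stage": "simulate", "n_persons": syn.n_persons, "seed": syn.seed})

    panel = preprocess.carry_forward_biennial(panel, outcomes=config.outcomes)

    graph = dag.build_default_graph(include_immigration=config.include_immigration)
    base_spec = dag.to_sem_spec(graph)

    results: dict = {}
    descriptives: dict = {}
    reports: dict = {}
    for out_i, outcome in enumerate(config.outcomes):
        table, report = preprocess.build_analysis_table(
            panel, outcome, collapse=config.collapse)
        reports[outcome] = report
        provenance["stages"].append(
            {"stage": f"preprocess:{outcome}", "persons": int(table.shape[0])})
        descriptives[outcome] = describe_population(table, outcomes=(outcome,))

        has_missing = table.drop(columns=["person_id"]).isna().any().any()
        if has_missing:
            method_map = impute.infer_method_map(
                table, exclude=("person_id", "weight", "age", "age10",
                                "sex_binary", f"{outcome}_incident"))
            imps = impute.impute_mice(
                table, m=config.m, method_map=method_map,
                seed=config.seed * 1000 + out_i,
                iterations=config.mice_iterations,
                protect=(f"{outcome}_incident",))
            datasets = imps.datasets
            provenance["stages"].append(
                {"stage": f"impute:{outcome}", **imps.manifest()})
        else:
            datasets = [table]
            provenance["stages"].append(
                {"stage": f"impute:{outcome}", "m": 1,
                 "note": "no missing cells; single complete dataset"})

        spec = adapt_spec_to_columns(base_spec, outcome)
        res_out: dict = {}
        for variant in config.variants:
            try:
                if variant == "main":
                    res_out[variant] = _pool_block(spec, datasets, weighted=False)
                elif variant == "weighted":
                    res_out[variant] = _pool_block(spec, datasets, weighted=True)
                elif variant == "sensitivity-no-sex-link":
                    res_out[variant] = _pool_block(
                        _drop_sex_link(spec), datasets, weighted=False)
                elif variant == "age-stratified":
                    strata = {}
                    for grp in preprocess.AGE_LABELS:
                        subsets = [d[d["age_group"] == grp] for d in datasets]
                        if min(len(s) for s in subsets) < 50:
                            strata[grp] = {"failure": "stratum too small"}
                            continue
                        strata[grp] = _pool_block(spec, subsets, weighted=False)
                    res_out[variant] = strata
            except Exception as exc:  # preserve partial results
                res_out[variant] = {"failure": f"{type(exc).__name__}: {exc}"}
        results[outcome] = res_out
    provenance["stages"].append({"stage": "done"})
    return StudyResults(results=results, descriptives=descriptives,
                        exclusion_reports=reports, provenance=provenance)


def describe_population(
    table: pd.DataFrame, weights: np.ndarray | None = None,
    outcomes=("migraine", "stroke"),
) -> dict:
    """Table-1-shaped descriptives by sex and overall.

    Continuous variables: mean, SD, median, min, max.  Categorical variables:
    counts and percentages (percentages within each sex column sum to 100 up
    to rounding).
    """
    if table.empty:
        raise ValueError("empty analysis table")
    w = np.ones(len(table)) if weights is None else np.asarray(weights, float)
    groups = {"male": table["sex"] == "male",
              "female": table["sex"] == "female",
              "overall": pd.Series(True, index=table.index)}
    out: dict = {}
    for gname, mask in groups.items():
        sub = table[mask.to_numpy()]
        ww = w[mask.to_numpy()]
        n = float(ww.sum())
        block = {"n": int(mask.sum())}
        age = sub["age"].to_numpy(dtype=float)
        mean = float(np.average(age, weights=ww))
        var = float(np.average((age - mean) ** 2, weights=ww))
        var *= len(age) / max(len(age) - 1, 1)
        block["age"] = {
            "mean": mean, "sd": float(np.sqrt(var)),
            "median": float(np.median(age)),
            "min": float(age.min()), "max": float(age.max()),
        }
        for cat in ("age_group", "sexual_orientation", "partner", "children",
                    "immigration"):
            if cat not in sub:
                continue
            col = sub[cat]
            counts = col.value_counts(dropna=False)
            block[cat] = {
                ("Missing" if (isinstance(k, float) and np.isnan(k)) or k is None
                 else str(k)): {
                    "count": int(v), "percent": float(100.0 * v / len(sub))}
                for k, v in counts.items()
            }
        for outc in outcomes:
            col = f"{outc}_incident"
            if col in sub:
                cases = int(sub[col].sum())
                block[f"{outc}_incidence"] = {
                    "cases": cases,
                    "percent": float(100.0 * cases / len(sub)),
                }
        out[gname] = block
    return out


def cumulative_incidence(cases, denominators) -> dict:
    """Cumulative incidence proportions, optionally by group, with the
    female/male ratio when both groups are present.

    Scalars give one proportion; dicts keyed by group give one per group.
    Percentages are rounded to one decimal for display only ("percent_display");
    stored values keep full precision.
    """
    if np.isscalar(cases):
        cases = {"overall": cases}
        denominators = {"overall": denominators}
    out: dict = {}
    for key, c in cases.items():
        d = denominators[key]
        if d <= 0:
            raise ZeroDivisionError(f"zero denominator for {key!r}")
        p = c / d
        out[key] = {"cases": int(c), "denominator": int(d),
                    "proportion": float(p),
                    "percent": float(100.0 * p),
                    "percent_display": round(100.0 * p, 1)}
    if {"female", "male"} <= set(out):
        ratio = out["female"]["proportion"] / out["male"]["proportion"]
        out["female_male_ratio"] = {"ratio": float(ratio),
                                    "ratio_display": round(ratio, 1)}
    return out
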