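"""Selection response, selection differentials, and realized heritability.

Realized heritability is the slope of cumulative selection response on
cumulative selection differential.  Response per generation, G, is the
difference between the selected-line mean and the contemporaneous
control-line mean of the trait; the within-family selection differential is
the selected animal's trait value minus the mean of its same-sex candidate
sibs, averaged over families and sexes within the line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

PHENOTYPE_COLUMNS = [
    "individual", "contacting", "heading", "sex", "generation", "family", "group", "selected",
]


def validate_phenotypes(phenotypes: pd.DataFrame, candidates_per_sex: int = 5) -> list[str]:
    """Invariant checks for a phenotype table; returns violations."""
    problems = []
    missing = [c for c in PHENOTYPE_COLUMNS if c not in phenotypes.columns]
    if missing:
        return [f"missing columns {missing}"]
    for trait in ("contacting", "heading"):
        if (phenotypes[trait] < 0).any():
            problems.append(f"negative {trait} durations")
    sizes = phenotypes.groupby(["group", "generation", "family", "sex"]).size()
    if (sizes > candidates_per_sex).any():
        problems.append(
            f"some (family, sex) cells exceed {candidates_per_sex} candidates"
        )
    return problems


@dataclass
class ResponseSeries:
    """Per-generation selected/control means and their difference G."""

    table: pd.DataFrame  # generation, selected_mean, control_mean, G
    mean_G: float
    selected_group: str = ""
    control_group: str = ""
    trait: str = "contacting"


@dataclass
class DifferentialSeries:
    """Per-generation within-family selection differentials and their cumsum."""

    table: pd.DataFrame  # generation, s, S_c
    group: str = ""
    trait: str = "contacting"


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    table: pd.DataFrame  # generation, R, S_c
    diagnostics: dict


def selection_response(
    phenotypes: pd.DataFrame,
    selected_group: str,
    control_group: str,
    trait: str = "contacting",
) -> ResponseSeries:
    """G_t = selected-line mean - control-line mean, per common generation."""
    sel = phenotypes[phenotypes["group"] == selected_group]
    ctl = phenotypes[phenotypes["group"] == control_group]
    sel_means = sel.groupby("generation")[trait].mean()
    ctl_means = ctl.groupby("generation")[trait].mean()
    common = sorted(set(sel_means.index) & set(ctl_means.index))
    if len(common) < 2:
        raise ValueError(
            f"groups {selected_group!r} and {control_group!r} share "
            f"{len(common)} generations; need >= 2"
        )
    table = pd.DataFrame(
        {
            "generation": common,
            "selected_mean": sel_means.loc[common].to_numpy(),
            "control_mean": ctl_means.loc[common].to_numpy(),
        }
    )
    table["G"] = table["selected_mean"] - table["control_mean"]
    return ResponseSeries(
        table=table,
        mean_G=float(table["G"].mean()),
        selected_group=selected_group,
        control_group=control_group,
        trait=trait,
    )


def selection_differentials(
    phenotypes: pd.DataFrame,
    trait: str = "contacting",
    group: str | None = None,
    method: str = "within-family",
) -> DifferentialSeries:
    """Per-generation selection differential s_t and its cumulative sum.

    ``method="within-family"`` (default): for each (family, sex) cell with a
    selected animal, s = selected value - mean of all same-sex candidates in
    the family; cell values are averaged within the line per generation.
    ``method="parent-offspring"`` is the literal variant: selected parents'
    mean minus the mean of their measured offspring in the next generation,
    per family, averaged within the line.
    """
    sub = phenotypes if group is None else phenotypes[phenotypes["group"] == group]
    if not sub["selected"].any():
        raise ValueError("no selected individuals in the chosen group")

    rows = []
    if method == "within-family":
        for gen, gen_df in sub.groupby("generation"):
            cells = []
            for (fam, sex), cell in gen_df.groupby(["family", "sex"]):
                picked = cell[cell["selected"]]
                if picked.empty:
                    continue
                if len(cell) == len(picked):
                    warnings.warn(
                        f"generation {gen} family {fam} sex {sex}: selected "
                        "individual has no candidate records; excluded"
                    )
                    continue
                cells.append(float(picked[trait].mean() - cell[trait].mean()))
            if cells:
                rows.append({"generation": gen, "s": float(np.mean(cells))})
    elif method == "parent-offspring":
        gens = sorted(sub["generation"].unique())
        for gen, nxt in zip(gens[:-1], gens[1:]):
            cur = sub[(sub["generation"] == gen) & sub["selected"]]
            off = sub[sub["generation"] == nxt]
            cells = []
            for fam, fam_off in off.groupby("family"):
                parents = cur  # line-level parents; family links are not
                # tracked across generations in the phenotype table, so the
                # literal variant compares line means
                cells.append(float(parents[trait].mean() - fam_off[trait].mean()))
            if cells:
                rows.append({"generation": gen, "s": float(np.mean(cells))})
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(rows, columns=["generation", "s"])
    table["S_c"] = table["s"].cumsum()
    return DifferentialSeries(table=table, group=group or "", trait=trait)


def realized_heritability(
    series: ResponseSeries,
    differentials: DifferentialSeries,
    se_method: str = "regression",
    lag: int = 1,
) -> HeritabilityEstimate:
    """Slope of cumulative response on cumulative selection differential.

    The regression is through the origin: zero cumulative differential
    implies zero expected response.  Cumulative response at generation t is
    R(t) = G(t) - G(t0); the differential from selecting breeders at
    generation t acts on generation t + ``lag``, so S_c is shifted by
    ``lag`` generations before aligning.  ``se_method="regression"`` is the
    usual OLS slope standard error; ``"response-ratio"`` divides the
    sampling variance of the responses by the final cumulative differential.
    """
    resp = series.table.set_index("generation")["G"]
    gens = sorted(resp.index)
    g0 = gens[0]
    R = resp.loc[gens] - resp.loc[g0]

    diff = differentials.table.set_index("generation")["S_c"]
    shifted = diff.copy()
    shifted.index = shifted.index + lag
    S = pd.Series(0.0, index=gens)
    acc = 0.0
    for g in gens:
        if g in shifted.index:
            acc = float(shifted.loc[g])
        S.loc[g] = acc

    aligned = pd.DataFrame({"generation": gens, "R": R.to_numpy(), "S_c": S.to_numpy()})
    fit_rows = aligned[aligned["S_c"] != 0.0]
    if fit_rows.empty:
        raise ValueError("all cumulative differentials are zero; h2 undefined")
    if len(aligned) < 2:
        raise ValueError("need >= 2 generations with both R and S_c")

    x = fit_rows["S_c"].to_numpy()
    y = fit_rows["R"].to_numpy()
    h2 = float(np.dot(x, y) / np.dot(x, x))
    resid = y - h2 * x
    dof = max(len(x) - 1, 1)
    se_reg = float(np.sqrt((resid @ resid) / dof / np.dot(x, x)))
    if se_method == "regression":
        se = se_reg
    elif se_method == "response-ratio":
        se = float(np.var(y, ddof=1) / x[-1]) if len(y) > 1 else float("nan")
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    with_const = sm.OLS(y, sm.add_constant(x)).fit() if len(x) > 2 else None
    diagnostics = {
        "n_points": int(len(x)),
        "se_regression": se_reg,
        "intercept_fit_slope": float(with_const.params[1]) if with_const is not None else float("nan"),
        "intercept_fit_intercept": float(with_const.params[0]) if with_const is not None else float("nan"),
        "r_squared_origin": float(1.0 - (resid @ resid) / (y @ y)) if (y @ y) > 0 else float("nan"),
    }
    return HeritabilityEstimate(h2=h2, se=se, table=aligned, diagnostics=diagnostics)
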