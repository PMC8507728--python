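"""Per-genus rank-regression associations of clr abundance with clinical
covariates, one sample type at a time, including the grade x location
interaction analysis.

Every model is a Jaeckel/Wilcoxon rank regression; the overall p-value per
genus is a drop-in-dispersion test of the covariate terms against the
nested model without them; q-values are BH within the (sample type x
model) family.  Only genera present in at least ``incidence_min`` samples
of some clinical group are tested.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import rankreg
from .io import GenusCountTable
from .stats import benjamini_hochberg

__all__ = [
    "LOCATION_GROUPS",
    "location_group",
    "incidence_filter",
    "simple_association",
    "grade_location_interaction",
    "covariate_encodings",
]

# the three-way regrouping of the five localisation labels used to keep the
# grade x location design reasonably balanced
LOCATION_GROUPS = {
    "right": "right_transverse",
    "transverse": "right_transverse",
    "left": "left",
    "rectosigmoideum": "rectosigmoid_rectum",
    "rectum": "rectosigmoid_rectum",
}


def location_group(localisation: pd.Series) -> pd.Series:
    unknown = set(localisation.dropna()) - set(LOCATION_GROUPS)
    if unknown:
        raise ValueError(f"unknown localisation labels: {sorted(unknown)}")
    return localisation.map(LOCATION_GROUPS)


def incidence_filter(
    counts: pd.DataFrame, grouping: pd.Series, min_samples: int = 10
) -> list[str]:
    """Genera present (count > 0) in >= ``min_samples`` samples of at least
    one clinical group."""
    grouping = grouping.loc[counts.columns]
    keep = []
    presence = counts > 0
    for genus in counts.index:
        by_group = presence.loc[genus].groupby(grouping).sum()
        if (by_group >= min_samples).any():
            keep.append(genus)
    return keep


def covariate_encodings(clinical: pd.DataFrame) -> dict[str, pd.Series]:
    """The standard single-covariate codings: ordinal grade, location
    contrasts, and binary stage dichotomies (advanced vs early)."""
    enc: dict[str, pd.Series] = {}
    grade = pd.to_numeric(clinical["grade"], errors="coerce")  # NA_in_situ -> NaN
    enc["grade_ordinal"] = grade
    lg = location_group(clinical["localisation"])
    enc["right_transverse_vs_rest"] = (lg == "right_transverse").astype(float)
    enc["left_vs_rest"] = (lg == "left").astype(float)
    enc["rectosigmoid_rectum_vs_rest"] = (lg == "rectosigmoid_rectum").astype(float)
    enc["ajcc_advanced"] = clinical["ajcc"].map(
        {"0": 0.0, "I": 0.0, "II": 0.0, "III": 1.0, "IV": 1.0}
    )
    enc["pT_late"] = clinical["pT"].map(
        {"pTis": 0.0, "pT1": 0.0, "pT2": 0.0, "pT3": 1.0, "pT4": 1.0}
    )
    enc["pN_positive"] = clinical["pN"].map({"pN0": 0.0, "pN1": 1.0, "pN2": 1.0})
    enc["M1"] = clinical["M"].map({"M0": 0.0, "M1": 1.0})
    return enc


def _clr_for_samples(clr_values: pd.DataFrame, table: GenusCountTable, sample_type: str):
    ids = table.samples_of_type(sample_type)
    meta = table.sample_meta.loc[ids]
    return clr_values[ids], meta["patient_id"]


def simple_association(
    clr_values: pd.DataFrame,
    table: GenusCountTable,
    covariate: pd.Series,
    sample_type: str,
    model: str,
    incidence_min: int = 10,
    fdr: float = 0.1,
    eligible: list[str] | None = None,
) -> pd.DataFrame:
    """One-covariate rank-regression screen for one sample type.

    ``covariate`` is indexed by patient_id (numeric; NaN rows dropped).
    Returns a long-format frame: genus, direction, p (drop-in-dispersion
    vs intercept-only), q (BH within this sample type x model family), n.
    """
    values, patients = _clr_for_samples(clr_values, table, sample_type)
    cov = covariate.reindex(patients.to_numpy()).astype(float)
    ok = ~cov.isna().to_numpy()
    values = values.iloc[:, ok]
    cov_arr = cov.to_numpy()[ok]
    if np.unique(cov_arr).size < 2:
        raise ValueError("covariate has fewer than 2 distinct values with data")
    counts_sub = table.counts[values.columns]
    if eligible is None:
        grouping = pd.Series(cov_arr, index=values.columns)
        eligible = incidence_filter(counts_sub, grouping, incidence_min)
    x = cov_arr[:, None]
    rows = []
    for genus in eligible:
        y = values.loc[genus].to_numpy()
        if np.all(y == y[0]):
            rows.append({"genus": genus, "beta": 0.0, "direction": "none", "p": 1.0,
                         "n": y.size})
            continue
        full = rankreg.fit(x, y, columns=[model])
        null = rankreg.fit(np.empty((y.size, 0)), y, columns=[])
        test = rankreg.drop_in_dispersion(full, null)
        rows.append(
            {
                "genus": genus,
                "beta": float(full.beta[0]),
                "direction": "up" if full.beta[0] > 0 else "down",
                "p": test.p_value,
                "n": y.size,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
        out["suggestive"] = out["p"] < 0.05
    out.insert(0, "model", model)
    out.insert(0, "sample_type", sample_type)
    return out


def _interaction_design(grade: np.ndarray, loc: np.ndarray):
    """Treatment-coded design for grade + location + grade:location over
    the observed (non-empty) cells; returns (X_full, X_reduced, cell_cols).
    Empty cells simply contribute no interaction column."""
    g_levels = sorted(np.unique(grade))
    l_levels = sorted(np.unique(loc))
    cols_red, names_red = [], []
    for g in g_levels[1:]:
        cols_red.append((grade == g).astype(float))
        names_red.append(f"grade[{g}]")
    for l in l_levels[1:]:
        cols_red.append((loc == l).astype(float))
        names_red.append(f"loc[{l}]")
    x_red = np.column_stack(cols_red) if cols_red else np.empty((len(grade), 0))
    # add interaction columns only while they keep the centred design full
    # rank: a sparse cell can make its indicator collinear with the main
    # effects (e.g. a grade observed in a single location group)
    cols = list(cols_red)
    names = list(names_red)
    for g in g_levels[1:]:
        for l in l_levels[1:]:
            col = ((grade == g) & (loc == l)).astype(float)
            if col.sum() == 0:
                continue
            cand = np.column_stack(cols + [col])
            if np.linalg.matrix_rank(cand - cand.mean(axis=0)) == cand.shape[1]:
                cols.append(col)
                names.append(f"grade[{g}]:loc[{l}]")
    x_full = np.column_stack(cols)
    return x_full, names, x_red, names_red


def grade_location_interaction(
    clr_values: pd.DataFrame,
    table: GenusCountTable,
    clinical: pd.DataFrame,
    sample_type: str = "tumour",
    incidence_min: int = 10,
    fdr: float = 0.1,
    eligible: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction screen: clr ~ grade + location + grade:location versus
    the additive model, compared by drop-in-dispersion per genus.

    Grade enters as a 3-level factor (in-situ/ungraded tumours excluded).
    For genera whose interaction is significant at ``fdr``, per-cell
    effects are reported: the cell's deviation indicator is added to the
    additive model, its coefficient sign gives the direction, and a
    drop-in-dispersion test of that single column gives the cell p-value.
    Returns (interaction results, per-cell contrasts).
    """
    values, patients = _clr_for_samples(clr_values, table, sample_type)
    clin = clinical.reindex(patients.to_numpy())
    grade = pd.to_numeric(clin["grade"], errors="coerce").to_numpy()
    loc = location_group(clin["localisation"]).to_numpy()
    ok = ~np.isnan(grade) & pd.notna(loc)
    values = values.iloc[:, ok]
    grade = grade[ok].astype(int)
    loc = loc[ok]

    cells, cell_counts = np.unique(
        [f"{g}|{l}" for g, l in zip(grade, loc)], return_counts=True
    )
    empty = 9 - len(cells)
    if empty:
        warnings.warn(f"{empty} empty grade x location cells; design reduced")

    x_full, names_full, x_red, names_red = _interaction_design(grade, loc)
    if np.linalg.matrix_rank(x_full - x_full.mean(axis=0)) < x_full.shape[1]:
        raise ValueError("interaction design not estimable after dropping empty cells")

    counts_sub = table.counts[values.columns]
    if eligible is None:
        grouping = pd.Series([f"{g}|{l}" for g, l in zip(grade, loc)], index=values.columns)
        eligible = incidence_filter(counts_sub, grouping, incidence_min)

    rows = []
    fits = {}
    for genus in eligible:
        y = values.loc[genus].to_numpy()
        if np.all(y == y[0]):
            rows.append({"genus": genus, "p": 1.0, "n": y.size})
            continue
        full = rankreg.fit(x_full, y, columns=names_full)
        red = rankreg.fit(x_red, y, columns=names_red)
        test = rankreg.drop_in_dispersion(full, red)
        fits[genus] = (y, red)
        rows.append({"genus": genus, "p": test.p_value, "n": y.size})
    inter = pd.DataFrame(rows)
    if len(inter):
        inter["q"] = benjamini_hochberg(inter["p"].to_numpy())
        inter["significant"] = inter["q"] < fdr
    inter.insert(0, "model", "grade_x_location")
    inter.insert(0, "sample_type", sample_type)

    cell_rows = []
    sig = inter.loc[inter.get("significant", pd.Series(dtype=bool)) == True, "genus"]
    for genus in sig:
        y, red = fits[genus]
        for cell in cells:
            g, l = cell.split("|")
            ind = ((grade == int(g)) & (loc == l)).astype(float)
            x_cell = np.column_stack([x_red, ind])
            if np.linalg.matrix_rank(x_cell - x_cell.mean(axis=0)) < x_cell.shape[1]:
                continue
            fit_cell = rankreg.fit(x_cell, y, columns=names_red + [f"cell[{cell}]"])
            t = rankreg.drop_in_dispersion(fit_cell, red)
            cell_rows.append(
                {
                    "genus": genus,
                    "grade": g,
                    "location": l,
                    "effect": float(fit_cell.beta[-1]),
                    "direction": "up" if fit_cell.beta[-1] > 0 else "down",
                    "p": t.p_value,
                }
            )
    cells_df = pd.DataFrame(cell_rows)
    if len(cells_df):
        cells_df["q"] = benjamini_hochberg(cells_df["p"].to_numpy())
    return inter, cells_df
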