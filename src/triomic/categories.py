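"""Environment-preference categorisation of genera from paired abundance
and incidence comparisons across tumour mucosa, visually normal mucosa and
stool triplets.

A genus is screened with a Friedman test across the three environments
(clr abundances, paired by patient); genera passing the Friedman gate at
the chosen FDR get pairwise Wilcoxon signed-rank post-hoc tests, each
BH-corrected across genera.  The flag pattern then maps to one of:

  tumour            more abundant in tumour mucosa than stool
  mucosa            tumour, and also enriched in normal mucosa vs stool
  tumour_specific   tumour, and additionally enriched vs normal mucosa
  stool             stool above BOTH mucosal environments
  no_difference     no significant pairwise difference
  other             a significant pattern matching none of the rules

A parallel incidence screen (presence/absence) runs Cochran Q with
pairwise McNemar post-hocs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compositional import ClrMatrix
from .io import GenusCountTable, triplet_patients
from .stats import benjamini_hochberg, cochran_q, friedman, mcnemar, wilcoxon_signed_rank

__all__ = [
    "abundance_screen",
    "incidence_screen",
    "assign_categories",
    "summarise_fractions",
    "PAIRS",
]

PAIRS = (("tumour", "stool"), ("normal", "stool"), ("tumour", "normal"))


def _triplet_cube(values: pd.DataFrame, table: GenusCountTable) -> tuple[np.ndarray, list]:
    """Stack per-genus values into (genus, patient, environment) with
    environment order (tumour, normal, stool); triplet patients only."""
    patients = triplet_patients(table)
    if len(patients) < 3:
        raise ValueError("need at least 3 triplet patients")
    meta = table.sample_meta
    cols = {}
    for env in ("tumour", "normal", "stool"):
        lookup = meta.index[meta["sample_type"] == env]
        by_patient = pd.Series(lookup, index=meta.loc[lookup, "patient_id"])
        cols[env] = [by_patient[p] for p in patients]
    cube = np.stack(
        [values[cols[env]].to_numpy() for env in ("tumour", "normal", "stool")], axis=2
    )
    return cube, patients


def abundance_screen(
    clr: ClrMatrix, table: GenusCountTable, fdr: float = 0.1
) -> pd.DataFrame:
    """Per-genus Friedman q across environments plus gated pairwise
    Wilcoxon q-values and directions (sign of the median paired clr
    difference)."""
    cube, patients = _triplet_cube(clr.values, table)
    g = cube.shape[0]
    fried_p = np.ones(g)
    for i in range(g):
        fried_p[i] = friedman(cube[i]).p_value
    fried_q = benjamini_hochberg(fried_p)
    gate = fried_q < fdr

    out = pd.DataFrame(
        {"friedman_p": fried_p, "friedman_q": fried_q},
        index=pd.Index(clr.values.index, name="genus_id"),
    )
    env_idx = {"tumour": 0, "normal": 1, "stool": 2}
    for a, b in PAIRS:
        name = f"{a}_vs_{b}"
        p = np.full(g, np.nan)
        med = np.full(g, np.nan)
        for i in np.flatnonzero(gate):
            d = cube[i, :, env_idx[a]] - cube[i, :, env_idx[b]]
            p[i] = wilcoxon_signed_rank(d).p_value
            med[i] = float(np.median(d))
        q = np.full(g, np.nan)
        if gate.any():
            q[gate] = benjamini_hochberg(p[gate])
        out[f"{name}_p"] = p
        out[f"{name}_q"] = q
        out[f"{name}_median"] = med
        out[f"{name}_up"] = (q < fdr) & (med > 0)
        out[f"{name}_down"] = (q < fdr) & (med < 0)
    out["tumour_vs_stool_up"] = out["tumour_vs_stool_up"].fillna(False)
    out["stool_up"] = out["tumour_vs_stool_down"] & out["normal_vs_stool_down"]
    out.attrs["n_triplets"] = len(patients)
    return out


def incidence_screen(
    table: GenusCountTable, fdr: float = 0.1
) -> pd.DataFrame:
    """Cochran Q on presence/absence across environments with pairwise
    McNemar post-hocs (BH across genera); also reports mucosa-only genera
    (never detected in stool but detected on mucosa)."""
    presence = (table.counts > 0).astype(int)
    cube, patients = _triplet_cube(presence, table)
    g = cube.shape[0]
    q_p = np.ones(g)
    for i in range(g):
        q_p[i] = cochran_q(cube[i]).p_value
    q_q = benjamini_hochberg(q_p)
    out = pd.DataFrame(
        {"cochran_p": q_p, "cochran_q_value": q_q},
        index=pd.Index(table.counts.index, name="genus_id"),
    )
    env_idx = {"tumour": 0, "normal": 1, "stool": 2}
    for a, b in PAIRS:
        p = np.array(
            [mcnemar(cube[i, :, env_idx[a]], cube[i, :, env_idx[b]]).p_value for i in range(g)]
        )
        out[f"{a}_vs_{b}_mcnemar_p"] = p
        out[f"{a}_vs_{b}_mcnemar_q"] = benjamini_hochberg(p)
    for env in ("tumour", "normal", "stool"):
        out[f"incidence_{env}"] = cube[:, :, env_idx[env]].mean(axis=1)
    out["mucosa_only"] = (
        (out["incidence_stool"] == 0)
        & ((out["incidence_tumour"] > 0) | (out["incidence_normal"] > 0))
    )
    out.attrs["n_triplets"] = len(patients)
    return out


def assign_categories(screen: pd.DataFrame) -> pd.DataFrame:
    """Map the abundance flag pattern of each genus to its category.

    A pure function of the four flags; mucosa and tumour_specific are
    subsets of tumour, with tumour_specific taking precedence when both
    apply (the more specific label).
    """
    cats = []
    for _, row in screen.iterrows():
        tvs_up = bool(row["tumour_vs_stool_up"])
        nvs_up = bool(row.get("normal_vs_stool_up", False) or False)
        tvn_up = bool(row.get("tumour_vs_normal_up", False) or False)
        stool_up = bool(row.get("stool_up", False) or False)
        any_sig = any(
            bool(row.get(f"{a}_vs_{b}_{d}", False) or False)
            for a, b in PAIRS
            for d in ("up", "down")
        )
        if tvs_up:
            if tvn_up:
                cats.append("tumour_specific")
            elif nvs_up:
                cats.append("mucosa")
            else:
                cats.append("tumour")
        elif stool_up:
            cats.append("stool")
        elif not any_sig:
            cats.append("no_difference")
        else:
            cats.append("other")
    out = screen.copy()
    out["category"] = cats
    out["tumour_flag"] = out["category"].isin(("tumour", "mucosa", "tumour_specific"))
    return out


def summarise_fractions(
    categories: pd.DataFrame, table: GenusCountTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tumour-sample summed relative abundance (%) of tumour-category
    and tumour-specific genera, plus min/median/max summaries."""
    tumour_ids = table.samples_of_type("tumour")
    counts = table.counts[tumour_ids]
    rel = counts / counts.sum(axis=0)
    tumour_set = categories.index[categories["tumour_flag"]]
    ts_set = categories.index[categories["category"] == "tumour_specific"]
    per_sample = pd.DataFrame(
        {
            "tumour_fraction": 100.0 * rel.loc[rel.index.intersection(tumour_set)].sum(axis=0),
            "tumour_specific_fraction": 100.0 * rel.loc[rel.index.intersection(ts_set)].sum(axis=0),
        }
    )
    summary = per_sample.agg(["min", "median", "max"]).T
    return per_sample, summary
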