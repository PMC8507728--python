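"""Compositional hierarchical subtyping of tumours on tumour-genus clr
profiles, genus co-clustering (B-groups), and the derived per-tumour
scores: oral fraction and microbial pathogens burden.

Tumour samples are clustered on the Aitchison distance between their
clr-transformed subcompositions over the tumour-genus list; genera are
clustered on the Euclidean distance between their clr profile rows.  Both
trees are cut at fixed k (3 tumour subtypes, 6 genus groups).  Subtype
labels are canonicalised (TMS1 = highest median pathogen burden when a
panel is available, otherwise smallest subtype first) so labels are stable
across runs; each subtype is re-cut in two for the a/b subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .compositional import ClrMatrix, clr_transform_counts
from .io import GenusCountTable
from .stats import TestResult, benjamini_hochberg, chi2_contingency, fisher_exact, kruskal_wallis, mann_whitney

__all__ = [
    "SubtypeResult",
    "subtype_cluster",
    "subtype_profiles",
    "oral_fraction",
    "pathogen_burden",
]


@dataclass
class SubtypeResult:
    """Tumour subtype (TMS) and genus group (B) assignments."""

    assignments: pd.DataFrame   # index sample_id: tms (1..k), subgroup ('a'/'b')
    genus_groups: pd.DataFrame  # index genus_id: bgroup (1..k_genera)
    sample_newick: str
    genus_newick: str
    linkage_method: str
    clr: ClrMatrix = field(repr=False, default=None)

    def tms_labels(self) -> pd.Series:
        return "TMS" + self.assignments["tms"].astype(str)


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    from scipy.cluster.hierarchy import to_tree

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(to_tree(z)) + ";"


def subtype_cluster(
    table: GenusCountTable,
    tumour_genera,
    k_samples: int = 3,
    k_genera: int = 6,
    linkage_method: str = "ward",
    pathogen_panel=None,
) -> SubtypeResult:
    """Cluster tumours into k subtypes and genera into k groups.

    The count table is restricted to tumour samples and the tumour-genus
    list, re-closed as a subcomposition, zero-replaced and
    clr-transformed.  Deterministic given inputs and linkage.  Subtype
    labels are ordered by decreasing median pathogen burden when
    ``pathogen_panel`` is given, else by increasing subtype size; genus
    groups by decreasing median incidence.
    """
    genera = [g for g in tumour_genera if g in table.genus_ids]
    if not genera:
        raise ValueError("tumour-genus list is disjoint from the table")
    tumour_ids = table.samples_of_type("tumour")
    if len(tumour_ids) < k_samples:
        raise ValueError("fewer tumour samples than requested clusters")
    sub = table.counts.loc[genera, tumour_ids]
    clr = clr_transform_counts(sub)

    sample_d = pdist(clr.values.to_numpy().T, metric="euclidean")  # Aitchison
    genus_d = pdist(clr.values.to_numpy(), metric="euclidean")
    z_samples = linkage(sample_d, method=linkage_method)
    z_genera = linkage(genus_d, method=linkage_method)
    raw_tms = fcluster(z_samples, k_samples, criterion="maxclust")
    raw_b = fcluster(z_genera, min(k_genera, len(genera)), criterion="maxclust")

    # canonical subtype order
    order_stat = {}
    for lab in np.unique(raw_tms):
        members = [tumour_ids[i] for i in np.flatnonzero(raw_tms == lab)]
        # ties broken on the lexicographically smallest member, so the
        # labelling is invariant to sample order
        if pathogen_panel is not None:
            burden = pathogen_burden(table, pathogen_panel).loc[members, "burden"]
            order_stat[lab] = (-float(burden.median()), min(members))
        else:
            order_stat[lab] = (len(members), min(members))
    relabel = {old: i + 1 for i, old in enumerate(sorted(order_stat, key=order_stat.get))}
    tms = np.array([relabel[t] for t in raw_tms])

    # a/b subgroups: re-cut each subtype's members in two
    subgroup = np.array(["a"] * len(tumour_ids), dtype=object)
    for lab in np.unique(tms):
        idx = np.flatnonzero(tms == lab)
        if idx.size >= 2:
            sub_d = pdist(clr.values.to_numpy().T[idx], metric="euclidean")
            z = linkage(sub_d, method=linkage_method)
            halves = fcluster(z, 2, criterion="maxclust")
            # 'a' = the larger half; ties broken on the smallest member id
            sizes = {
                h: (
                    -(halves == h).sum(),
                    min(tumour_ids[idx[j]] for j in np.flatnonzero(halves == h)),
                )
                for h in (1, 2)
            }
            a_label = min(sizes, key=sizes.get)
            subgroup[idx] = np.where(halves == a_label, "a", "b")

    # canonical genus-group order: most prevalent group first
    incidence = (sub > 0).mean(axis=1)
    b_stat = {}
    for lab in np.unique(raw_b):
        idx_b = np.flatnonzero(raw_b == lab)
        members = incidence.iloc[idx_b]
        b_stat[lab] = (-float(members.median()), min(genera[j] for j in idx_b))
    b_relabel = {old: i + 1 for i, old in enumerate(sorted(b_stat, key=b_stat.get))}
    bgroups = np.array([b_relabel[b] for b in raw_b])

    assignments = pd.DataFrame(
        {"tms": tms, "subgroup": subgroup},
        index=pd.Index(tumour_ids, name="sample_id"),
    )
    genus_groups = pd.DataFrame(
        {"bgroup": bgroups}, index=pd.Index(genera, name="genus_id")
    )
    return SubtypeResult(
        assignments=assignments,
        genus_groups=genus_groups,
        sample_newick=_linkage_to_newick(z_samples, tumour_ids),
        genus_newick=_linkage_to_newick(z_genera, genera),
        linkage_method=linkage_method,
        clr=clr,
    )


def subtype_profiles(
    result: SubtypeResult,
    table: GenusCountTable,
    clinical: pd.DataFrame,
    fdr: float = 0.1,
    categorical_test: str = "fisher",
    fisher_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-subtype differential genera (per environment) and clinical
    contingency tests.

    Per genus and environment: Kruskal-Wallis of clr abundance across
    subtypes plus pairwise Mann-Whitney, BH within environment.  Per
    clinical variable: an r x c test on the subtype x category table —
    ``categorical_test`` picks Fisher exact ("fisher") or Pearson
    chi-square ("chi2") — and Kruskal-Wallis for age.
    """
    from .compositional import clr_transform_counts

    tms = result.assignments["tms"]
    sizes = tms.value_counts()
    usable = sizes.index[sizes >= 2]
    if len(usable) < len(sizes):
        warnings.warn(f"subtypes with < 2 members excluded: {sorted(set(sizes.index) - set(usable))}")
    patient_of = table.sample_meta["patient_id"]
    subtype_of_patient = pd.Series(
        tms.values, index=patient_of.loc[tms.index].values
    )

    diff_rows = []
    for env in ("tumour", "normal", "stool"):
        ids = table.samples_of_type(env)
        if not ids:
            continue
        clr_env = clr_transform_counts(table.counts[ids])
        labels = subtype_of_patient.reindex(patient_of.loc[ids].values).to_numpy()
        ok = pd.notna(labels)
        ids_ok = [i for i, o in zip(ids, ok) if o]
        labels = labels[ok].astype(int)
        keep = np.isin(labels, usable.to_numpy())
        ids_ok = [i for i, k in zip(ids_ok, keep) if k]
        labels = labels[keep]
        for genus in table.genus_ids:
            vals = clr_env.values.loc[genus, ids_ok].to_numpy()
            groups = [vals[labels == t] for t in sorted(np.unique(labels))]
            if len(groups) < 2:
                continue
            kw = kruskal_wallis(*groups)
            row = {"environment": env, "genus": genus, "kw_p": kw.p_value}
            for i, a in enumerate(sorted(np.unique(labels))):
                for b in sorted(np.unique(labels))[i + 1 :]:
                    mw = mann_whitney(vals[labels == a], vals[labels == b])
                    row[f"mw_{a}_vs_{b}_p"] = mw.p_value
            diff_rows.append(row)
    diff = pd.DataFrame(diff_rows)
    if len(diff):
        for env in diff["environment"].unique():
            m = diff["environment"] == env
            diff.loc[m, "kw_q"] = benjamini_hochberg(diff.loc[m, "kw_p"].to_numpy())

    clin_rows = []
    clin = clinical.reindex(subtype_of_patient.index)
    for var in clin.columns:
        if var == "age":
            groups = [
                pd.to_numeric(clin.loc[subtype_of_patient == t, var]).dropna().to_numpy()
                for t in sorted(subtype_of_patient.unique())
            ]
            groups = [gr for gr in groups if gr.size]
            res = kruskal_wallis(*groups)
        else:
            ct = pd.crosstab(clin[var], subtype_of_patient)
            if ct.shape[0] < 2:
                continue
            if categorical_test == "chi2":
                res = chi2_contingency(ct.to_numpy())
            else:
                res = fisher_exact(ct.to_numpy(), **(fisher_kwargs or {}))
        clin_rows.append({"variable": var, "p": res.p_value, "method": res.method})
    return diff, pd.DataFrame(clin_rows)


def oral_fraction(
    table: GenusCountTable,
    annotation: pd.Series,
    assignments: pd.DataFrame | None = None,
) -> tuple[pd.Series, TestResult | None]:
    """Per-tumour summed relative abundance (%) of oral-annotated genera;
    Kruskal-Wallis across subtypes when assignments are given.

    ``annotation`` maps genus_id -> origin in {oral, gut, unknown}; genera
    missing from it count as unknown.
    """
    tumour_ids = table.samples_of_type("tumour")
    counts = table.counts[tumour_ids]
    origin = annotation.reindex(table.genus_ids).fillna("unknown")
    oral = origin.index[origin == "oral"]
    if len(oral) == 0:
        warnings.warn("no genus annotated as oral; fractions are all 0")
    rel = counts / counts.sum(axis=0)
    frac = 100.0 * rel.loc[rel.index.intersection(oral)].sum(axis=0)
    frac.name = "oral_fraction"
    test = None
    if assignments is not None:
        tms = assignments["tms"].reindex(tumour_ids)
        groups = [frac[tms == t].to_numpy() for t in sorted(tms.dropna().unique())]
        if len(groups) >= 2:
            test = kruskal_wallis(*groups)
    return frac, test


def pathogen_burden(table: GenusCountTable, panel) -> pd.DataFrame:
    """Per-tumour count of detected (count > 0) genera from the pathogen
    panel; panel genera missing from the table count as absent."""
    if not len(panel):
        raise ValueError("pathogen panel is empty")
    tumour_ids = table.samples_of_type("tumour")
    present_panel = [g for g in panel if g in table.genus_ids]
    missing = sorted(set(panel) - set(present_panel))
    if missing:
        warnings.warn(f"panel genera absent from table (counted absent): {missing}")
    if present_panel:
        burden = (table.counts.loc[present_panel, tumour_ids] > 0).sum(axis=0)
    else:
        burden = pd.Series(0, index=tumour_ids)
    out = pd.DataFrame({"burden": burden})
    out.index.name = "sample_id"
    out.attrs["panel_size"] = len(panel)
    return out
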