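"""Alpha diversity (observed genera, Chao1, Shannon) with paired
comparisons across environments, and Aitchison beta diversity with
PERMANOVA and PCoA ordination.

Alpha diversity is computed on unfiltered integer counts (the taxa filter
would bias richness estimates); Shannon entropy is reported in bits.
Ordination uses PCoA on the Aitchison distance matrix, which coincides
with PCA of the clr values up to sign.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1, shannon

from .compositional import ClrMatrix, aitchison_distance_matrix
from .io import GenusCountTable, triplet_patients
from .stats import benjamini_hochberg, permanova, wilcoxon_signed_rank

__all__ = ["alpha_diversity", "alpha_compare", "beta_permanova"]

_METRICS = ("observed", "chao1", "shannon")


def alpha_diversity(table: GenusCountTable) -> pd.DataFrame:
    """Observed richness, bias-corrected Chao1 and Shannon index (bits)
    per sample."""
    rows = {}
    for sid in table.sample_ids:
        c = table.counts[sid].to_numpy()
        if c.sum() == 0:
            raise ValueError(f"empty sample {sid}")
        rows[sid] = {
            "observed": int((c > 0).sum()),
            "chao1": float(chao1(c, bias_corrected=True)),
            "shannon": float(shannon(c, base=2)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def alpha_compare(
    alpha: pd.DataFrame, table: GenusCountTable, fdr: float = 0.1
) -> pd.DataFrame:
    """Paired signed-rank comparisons of each alpha metric between each
    environment pair over triplet patients; BH across the 9 tests."""
    patients = triplet_patients(table)
    if len(patients) < 3:
        raise ValueError("need at least 3 triplet patients")
    meta = table.sample_meta
    sample_of = {
        (p, t): sid
        for sid, (p, t) in meta[["patient_id", "sample_type"]].iterrows()
    }
    rows = []
    for metric in _METRICS:
        for a, b in itertools.combinations(("tumour", "normal", "stool"), 2):
            da = np.array([alpha.loc[sample_of[(p, a)], metric] for p in patients])
            db = np.array([alpha.loc[sample_of[(p, b)], metric] for p in patients])
            res = wilcoxon_signed_rank(da - db)
            rows.append(
                {
                    "metric": metric,
                    "pair": f"{a}_vs_{b}",
                    "median_diff": float(np.median(da - db)),
                    "p": res.p_value,
                    "n": len(patients),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def beta_permanova(
    clr: ClrMatrix,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way PERMANOVA of the Aitchison distance matrix against each
    covariate column separately, plus PCoA coordinates for plotting.

    ``covariates`` is indexed by sample_id (one sample type at a time);
    rows with missing covariate values are dropped per test.
    """
    from skbio.stats.ordination import pcoa
    from skbio.stats.distance import DistanceMatrix

    dist = aitchison_distance_matrix(clr.values)
    rows = []
    for i, col in enumerate(covariates.columns):
        vals = covariates[col].reindex(dist.index)
        ok = vals.notna().to_numpy()
        if vals[ok].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")
        d_ok = dist.to_numpy()[np.ix_(ok, ok)]
        res = permanova(d_ok, vals[ok].to_numpy(), n_perm=n_perm, seed=seed + i)
        rows.append(
            {
                "covariate": col,
                "pseudo_F": res.statistic,
                "R2": res.extra["R2"],
                "p": res.p_value,
                "n": int(ok.sum()),
            }
        )
    ord_res = pcoa(DistanceMatrix(dist.to_numpy(), ids=list(dist.index)), dimensions=2)
    coords = ord_res.samples.iloc[:, :2]
    coords.index = dist.index
    return pd.DataFrame(rows), coords
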