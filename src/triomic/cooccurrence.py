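"""Pairwise co-occurrence of tumour genera on tumour mucosa.

For each genus pair, a Fisher exact test on the 2 x 2 presence/absence
table over tumour samples, BH-corrected across pairs; a pair is an
increased co-occurrence when OR > 1 and q < fdr, decreased when OR < 1
and q < fdr.  A Spearman-on-clr alternative is available behind a flag
for users who prefer an abundance-based screen.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenusCountTable
from .stats import benjamini_hochberg, fisher_exact

__all__ = ["cooccurrence_screen"]


def cooccurrence_screen(
    table: GenusCountTable,
    genus_subset,
    fdr: float = 0.1,
    method: str = "fisher",
    clr_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Screen all pairs within ``genus_subset`` on tumour samples.

    Pairs involving a genus present in no tumour sample (or in all of
    them, for which the 2 x 2 table has a zero margin) are reported with
    status 'skipped'.  Results are symmetric in pair order.
    """
    genus_subset = sorted(set(genus_subset) & set(table.genus_ids))
    if len(genus_subset) < 2:
        raise ValueError("need at least 2 genera present in the table")
    tumour_ids = table.samples_of_type("tumour")
    presence = (table.counts.loc[genus_subset, tumour_ids] > 0).astype(int)

    rows = []
    for a, b in itertools.combinations(genus_subset, 2):
        pa = presence.loc[a].to_numpy()
        pb = presence.loc[b].to_numpy()
        if method == "spearman":
            if clr_values is None:
                raise ValueError("method='spearman' requires clr_values")
            rho, p = sps.spearmanr(
                clr_values.loc[a, tumour_ids], clr_values.loc[b, tumour_ids]
            )
            rows.append({"genus_a": a, "genus_b": b, "statistic": rho, "p": p,
                         "odds_ratio": np.nan, "status": "tested"})
            continue
        t = np.array(
            [
                [int(((pa == 1) & (pb == 1)).sum()), int(((pa == 1) & (pb == 0)).sum())],
                [int(((pa == 0) & (pb == 1)).sum()), int(((pa == 0) & (pb == 0)).sum())],
            ]
        )
        if pa.sum() == 0 or pb.sum() == 0:
            rows.append({"genus_a": a, "genus_b": b, "statistic": np.nan, "p": np.nan,
                         "odds_ratio": np.nan, "status": "skipped"})
            continue
        res = fisher_exact(t)
        if res.method == "fisher_exact_degenerate":
            rows.append({"genus_a": a, "genus_b": b, "statistic": np.nan, "p": np.nan,
                         "odds_ratio": res.extra.get("odds_ratio", np.nan),
                         "status": "skipped"})
            continue
        rows.append({"genus_a": a, "genus_b": b, "statistic": np.nan, "p": res.p_value,
                     "odds_ratio": res.extra["odds_ratio"], "status": "tested"})
    out = pd.DataFrame(rows)
    tested = out["status"] == "tested"
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    if method == "spearman":
        effect_up = out["statistic"] > 0
    else:
        effect_up = out["odds_ratio"] > 1
    out["direction"] = np.select(
        [tested & (q < fdr) & effect_up, tested & (q < fdr) & ~effect_up],
        ["increased", "decreased"],
        default="ns",
    )
    out.attrs["n_pairs_expected"] = len(genus_subset) * (len(genus_subset) - 1) // 2
    return out
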