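"""Group-level statistics: monthly climate aggregation, two-group Welch tests
for climate and photosynthesis parameters, and categorical over-representation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ttest_rel

from ._stats import bh_adjust, welch_ttest
from .clustering import AccessionGrouping
from .errors import GlknetError

log = logging.getLogger(__name__)

MONTH_COLUMNS = [f"month_{m:02d}" for m in range(1, 13)]


def _month_cols(climate: pd.DataFrame):
    cols = [c for c in climate.columns if c.startswith("month_")]
    if not cols:
        raise GlknetError("climate table has no month_* columns")
    return sorted(cols)


def monthly_summary(climate: pd.DataFrame, months: int = 12) -> pd.DataFrame:
    """Per accession x variable mean and sample SD (ddof=1) over the monthly values.

    ``climate`` has columns accession, variable, month_01..month_NN.
    """
    cols = _month_cols(climate)
    if len(cols) != months:
        raise GlknetError(f"expected {months} month columns, found {len(cols)}")
    vals = climate[cols].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise GlknetError("missing monthly values are not allowed")
    out = climate[["accession", "variable"]].copy()
    out["mean"] = vals.mean(axis=1)
    out["sd"] = vals.std(axis=1, ddof=1)
    return out


def group_ttest(values, groups: AccessionGrouping, group_a, group_b) -> dict:
    """Welch two-sided t-test of per-accession values between two groups.

    ``values`` maps accession -> value; accessions lacking a value or a group
    label are dropped (count logged).
    """
    series = pd.Series(dict(values), dtype=float).dropna()
    a = series[[i for i in series.index if groups.labels.get(i) == group_a]]
    b = series[[i for i in series.index if groups.labels.get(i) == group_b]]
    n_dropped = sum(1 for acc in groups.labels if acc not in series.index)
    if n_dropped:
        log.info("group_ttest: %d labeled accessions lack values", n_dropped)
    if len(a) < 2 or len(b) < 2:
        raise GlknetError("both groups need >=2 accessions with values")
    t, p, _, ma, mb = welch_ttest(a.to_numpy(), b.to_numpy())
    return {"mean_a": float(ma), "mean_b": float(mb), "t_stat": float(t),
            "p_value": float(p), "n_a": int(len(a)), "n_b": int(len(b))}


def climate_group_tests(climate: pd.DataFrame, groups: AccessionGrouping,
                        group_a, group_b, months: int = 12) -> pd.DataFrame:
    """Rank climate variables by how their per-accession monthly mean and SD
    differ between two groups (ascending raw p, BH q as an extra column)."""
    summ = monthly_summary(climate, months=months)
    rows = []
    for (variable, stat), sub in (
        summ.melt(id_vars=["accession", "variable"], value_vars=["mean", "sd"],
                  var_name="stat").groupby(["variable", "stat"], sort=True)
    ):
        vals = dict(zip(sub["accession"], sub["value"]))
        res = group_ttest(vals, groups, group_a, group_b)
        rows.append({"variable": variable, "stat": stat, **res})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def photosynthesis_group_tests(photo: pd.DataFrame, groups: AccessionGrouping,
                               group_ids, paired: bool = False) -> pd.DataFrame:
    """Within-group, across-condition contrasts of photosynthesis parameters.

    ``photo`` has columns accession, condition, parameter, value. For each
    requested group and each parameter, the two conditions are contrasted by
    an unpaired Welch t-test (or a paired t-test on accessions measured in
    both conditions with ``paired=True``). Only accessions present in both
    the table and the grouping are used.
    """
    conditions = sorted(photo["condition"].unique())
    if len(conditions) != 2:
        raise GlknetError(f"expected exactly 2 conditions, found {conditions}")
    c0, c1 = conditions
    rows = []
    for group_id in group_ids:
        members = {a for a, g in groups.labels.items() if g == group_id}
        sub = photo[photo["accession"].isin(members)]
        for parameter, psub in sub.groupby("parameter", sort=True):
            piv = psub.pivot_table(index="accession", columns="condition",
                                   values="value", aggfunc="mean")
            if paired:
                both = piv.dropna()
                if len(both) < 2:
                    raise GlknetError("paired test needs >=2 accessions in both conditions")
                t, p = ttest_rel(both[c0], both[c1])
                ma, mb = float(both[c0].mean()), float(both[c1].mean())
                na = nb = len(both)
            else:
                a = piv[c0].dropna().to_numpy() if c0 in piv else np.array([])
                b = piv[c1].dropna().to_numpy() if c1 in piv else np.array([])
                if len(a) < 2 or len(b) < 2:
                    raise GlknetError(
                        f"group {group_id} parameter {parameter}: <2 accessions per condition"
                    )
                t, p, _, ma, mb = welch_ttest(a, b)
                na, nb = len(a), len(b)
            rows.append({"group": group_id, "parameter": parameter,
                         f"mean_{c0}": float(ma), f"mean_{c1}": float(mb),
                         "t_stat": float(t), "p_value": float(p),
                         "n_a": int(na), "n_b": int(nb)})
    return pd.DataFrame(rows)


def overrepresentation(selected, universe, categories) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of category labels.

    ``categories`` maps item -> label (items without a label are counted only
    in the universe size). P(X >= k) per label, BH-adjusted across labels.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise GlknetError("selected set is empty")
    stray = selected - universe
    if stray:
        raise GlknetError(f"selected items absent from universe: {sorted(stray)[:5]}")
    m = len(universe)
    n_sel = len(selected)
    labels = sorted({categories[i] for i in universe if i in categories})
    rows = []
    for lab in labels:
        in_lab = {i for i in universe if categories.get(i) == lab}
        k = len(selected & in_lab)
        p = float(hypergeom.sf(k - 1, m, len(in_lab), n_sel))
        rows.append({"label": lab, "count_sel": k, "count_univ": len(in_lab),
                     "p_hypergeom": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q_bh"] = bh_adjust(out["p_hypergeom"].to_numpy())
    return out.sort_values("p_hypergeom", kind="mergesort").reset_index(drop=True)
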