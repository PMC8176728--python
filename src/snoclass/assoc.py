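"""Categorical and rank tests linking abundance/correlation classes to annotations.

Wraps the three test primitives the analysis relies on -- Fisher's exact
test on 2x2 tables, an exact conditional test for small 2xk tables, and the
two-sided Mann-Whitney U test -- and assembles them into the full
association battery relating the UE/TE abundance classes and the
correlation classes to snoRNA box type, target class, host-gene biotype and
function, NMD susceptibility, promoter architecture, conservation and
snoRNA-to-host abundance ratios.  Battery p-values are reported raw
(uncorrected); significance stars follow the usual convention
(* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import gammaln

from .errors import DataError

log = logging.getLogger(__name__)

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: Upper bound on the number of candidate tables enumerated by the exact
#: 2xk test before asking the caller to collapse categories.
_MAX_ENUMERATION = 5_000_000


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


@dataclass
class AssociationResult:
    """Outcome of one association test.

    ``statistic`` is the odds ratio for 2x2 Fisher tests, the U statistic
    for Mann-Whitney comparisons, and NaN for the exact 2xk test (which has
    no single-number effect size).  ``status`` is ``"ok"`` for a computed
    test or ``"skipped: <reason>"`` for a degenerate stratum.
    """

    test: str
    grouping: str
    statistic: float
    p: float
    n: int
    status: str = "ok"
    table: list = field(default_factory=list)

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def _check_counts(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if np.any(arr != np.floor(arr)):
        raise DataError("contingency table counts must be integers")
    if (arr < 0).any():
        raise DataError("contingency table counts must be non-negative")
    return arr.astype(np.int64)


def fisher_exact_2x2(table, grouping: str = "") -> AssociationResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) at most as probable as the observed one.  The
    reported odds ratio is the sample odds ratio ``ad/bc``; with a zero in
    ``b`` or ``c`` it is infinite (NaN if ``ad`` is also zero).
    """
    arr = _check_counts(table)
    if arr.shape != (2, 2):
        raise DataError("fisher_exact_2x2 requires a 2x2 table")
    (a, b), (c, d) = arr
    _, p = st.fisher_exact(arr, alternative="two-sided")
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return AssociationResult(
        test="fisher_exact", grouping=grouping, statistic=float(odds),
        p=float(p), n=int(arr.sum()), table=arr.tolist())


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2xk(table, grouping: str = "") -> AssociationResult:
    """Exact conditional test on a 2xk table (k <= 4) by full enumeration.

    All tables with the observed margins are enumerated; their conditional
    probabilities follow the multivariate hypergeometric distribution, and
    the two-sided p-value sums the probabilities of every table at most as
    probable as the observed one (probability-ordering rule, with a 1e-7
    relative tolerance on the comparison).  Raises :class:`DataError` when
    the margins would require enumerating more than a few million tables;
    collapse categories in that case.
    """
    arr = _check_counts(table)
    if arr.ndim != 2 or arr.shape[0] != 2 or not 2 <= arr.shape[1] <= 4:
        raise DataError("fisher_exact_2xk requires a 2xk table with 2 <= k <= 4")
    k = arr.shape[1]
    cols = arr.sum(axis=0)
    r1 = int(arr[0].sum())
    n = int(arr.sum())

    sizes = [min(int(c), r1) + 1 for c in cols[:-1]]
    if np.prod(sizes, dtype=float) > _MAX_ENUMERATION:
        raise DataError("margins too large for exact 2xk enumeration; "
                        "collapse categories or use a 2x2 comparison")

    axes = [np.arange(s) for s in sizes]
    grids = np.meshgrid(*axes, indexing="ij")
    last = r1 - sum(grids)
    valid = (last >= 0) & (last <= cols[-1])
    logp = np.zeros_like(grids[0], dtype=float)
    for j, g in enumerate(grids):
        logp += _log_binom(int(cols[j]), g)
    logp += _log_binom(int(cols[-1]), np.where(valid, last, 0))
    logp -= _log_binom(n, r1)
    logp_obs = (sum(_log_binom(int(cols[j]), int(arr[0, j])) for j in range(k))
                - _log_binom(n, r1))
    sel = valid & (logp <= logp_obs + 1e-7)
    p = float(np.exp(logp[sel]).sum())
    return AssociationResult(
        test="fisher_exact_2xk", grouping=grouping, statistic=math.nan,
        p=min(p, 1.0), n=n, table=arr.tolist())


def mann_whitney_u(x, y, grouping: str = "") -> AssociationResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both groups have at most 20
    observations and there are no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise.  If every value
    in both groups is identical the comparison is vacuous: p = 1 with a
    logged warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        log.warning("stage=assoc action=identical_values grouping=%s", grouping)
        return AssociationResult(
            test="mann_whitney_u", grouping=grouping,
            statistic=float(x.size * y.size / 2), p=1.0,
            n=int(combined.size))
    ties = np.unique(combined).size < combined.size
    method = "exact" if (max(x.size, y.size) <= 20 and not ties) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return AssociationResult(
        test="mann_whitney_u", grouping=grouping,
        statistic=float(res.statistic), p=float(res.pvalue),
        n=int(combined.size))


def _skip(test: str, grouping: str, reason: str) -> AssociationResult:
    log.info("stage=assoc action=skip test=%s grouping=%s reason=%s",
             test, grouping, reason)
    return AssociationResult(test=test, grouping=grouping,
                             statistic=math.nan, p=math.nan, n=0,
                             status=f"skipped: {reason}")


def _crosstab(df, rowcol, colcol, row_order, col_order):
    ct = pd.crosstab(df[rowcol], df[colcol])
    ct = ct.reindex(index=row_order, columns=col_order, fill_value=0)
    return ct.to_numpy()


def _fisher_auto(tab, name, grouping):
    """Dispatch to the 2x2 or exact 2xk test, dropping empty columns."""
    tab = np.asarray(tab)
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
        return _skip(name, grouping, "degenerate table")
    try:
        if tab.shape[1] == 2:
            res = fisher_exact_2x2(tab, grouping)
        else:
            res = fisher_exact_2xk(tab, grouping)
    except DataError as exc:
        return _skip(name, grouping, str(exc))
    res.test = name
    return res


def _mwu_auto(x, y, name, grouping):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        return _skip(name, grouping, "empty or all-unknown group")
    res = mann_whitney_u(x, y, grouping)
    res.test = name
    return res


def class_association_battery(
    assignments: pd.DataFrame,
    correlations: pd.DataFrame,
    annotation: pd.DataFrame,
    ratios: pd.DataFrame | None = None,
) -> list[AssociationResult]:
    """Run the full battery of class/annotation association tests.

    ``assignments`` carries the per-gene UE/TE labels, ``correlations`` the
    per-pair correlation classes, and ``annotation`` the gene attributes.
    Tests on degenerate strata (an empty class, an all-unknown column) are
    returned with a ``skipped`` status rather than dropped, so the battery
    output always has a stable shape.  All comparisons use
    pairwise-complete data: unknown annotation values are dropped per test.
    """
    results: list[AssociationResult] = []
    sno = assignments.join(annotation, how="left")
    classes = ("UE", "TE")
    has_te = (sno["abundance_class"] == "TE").any()
    has_ue = (sno["abundance_class"] == "UE").any()

    # (a) box type x abundance class
    if has_te and has_ue:
        sub = sno[sno["box_type"].isin(["CD", "HACA"])]
        results.append(_fisher_auto(
            _crosstab(sub, "abundance_class", "box_type", classes, ["CD", "HACA"]),
            "box_type_vs_class", "UE/TE x CD/HACA"))
    else:
        results.append(_skip("box_type_vs_class", "UE/TE x CD/HACA",
                             "one abundance class is empty"))

    # (b) target class x abundance class
    if has_te and has_ue:
        sub = sno[sno["target_class"].isin(["rRNA", "snRNA", "orphan"])]
        results.append(_fisher_auto(
            _crosstab(sub, "abundance_class", "target_class", classes,
                      ["rRNA", "snRNA", "orphan"]),
            "target_vs_class", "UE/TE x rRNA/snRNA/orphan"))
    else:
        results.append(_skip("target_vs_class", "UE/TE x target",
                             "one abundance class is empty"))

    # (c) host biotype group x abundance class
    if has_te and has_ue:
        sub = sno[sno["host_biotype_group"].isin(
            ["protein-coding", "non-coding", "intergenic"])]
        results.append(_fisher_auto(
            _crosstab(sub, "abundance_class", "host_biotype_group", classes,
                      ["protein-coding", "non-coding", "intergenic"]),
            "host_biotype_vs_class", "UE/TE x host biotype"))
    else:
        results.append(_skip("host_biotype_vs_class", "UE/TE x host biotype",
                             "one abundance class is empty"))

    # (d) conservation between abundance classes
    for col in ("conservation_vertebrates", "conservation_primates"):
        name = f"{col}_vs_class"
        if not (has_te and has_ue):
            results.append(_skip(name, "UE vs TE", "one abundance class is empty"))
            continue
        if col not in sno.columns:
            results.append(_skip(name, "UE vs TE", "annotation column absent"))
            continue
        ue = sno.loc[sno["abundance_class"] == "UE", col]
        te = sno.loc[sno["abundance_class"] == "TE", col]
        results.append(_mwu_auto(ue, te, name, "UE vs TE"))

    corr = correlations.merge(
        sno[["abundance_class", "host_biotype_group", "host_function_group",
             "nmd_substrate", "promoter_type"]
            + [c for c in ("conservation_vertebrates",) if c in sno.columns]],
        left_on="sno_gene_id", right_index=True, how="left")

    # (e) NMD x correlation class, stratified by abundance class and host biotype
    for cls in classes:
        for hb in ("protein-coding", "non-coding"):
            name = "nmd_vs_correlation"
            grouping = f"{cls}, {hb} hosts"
            sub = corr[(corr["abundance_class"] == cls)
                       & (corr["host_biotype_group"] == hb)
                       & corr["nmd_substrate"].notna()]
            if len(sub) == 0:
                results.append(_skip(name, grouping, "empty or all-unknown stratum"))
                continue
            sub = sub.assign(nmd=sub["nmd_substrate"].astype(bool))
            results.append(_fisher_auto(
                _crosstab(sub, "nmd", "correlation_class", [True, False],
                          ["anticorrelated", "non-correlated", "positive"]),
                name, grouping))

    # (f) host function group x correlation sign, protein-coding hosts
    for cls in classes:
        sub = corr[(corr["abundance_class"] == cls)
                   & (corr["host_biotype_group"] == "protein-coding")
                   & corr["correlation_class"].isin(["anticorrelated", "positive"])
                   & corr["host_function_group"].notna()
                   & (corr["host_function_group"] != "unknown")]
        for func in ("ribosomal protein", "RNA processing / ribosome biogenesis"):
            name = "host_function_vs_correlation_sign"
            grouping = f"{cls}, {func} vs other functions"
            if len(sub) == 0:
                results.append(_skip(name, grouping, "empty or all-unknown stratum"))
                continue
            sub2 = sub.assign(is_func=sub["host_function_group"] == func)
            results.append(_fisher_auto(
                _crosstab(sub2, "is_func", "correlation_class", [True, False],
                          ["anticorrelated", "positive"]),
                name, grouping))

    # (g) promoter type x correlation (rank test on r) and x abundance class
    for cls in classes:
        name = "promoter_vs_correlation"
        grouping = f"{cls}, DI vs SI"
        sub = corr[(corr["abundance_class"] == cls)
                   & corr["promoter_type"].isin(["DI", "SI"])]
        di = sub.loc[sub["promoter_type"] == "DI", "r"]
        si = sub.loc[sub["promoter_type"] == "SI", "r"]
        if len(di) == 0 or len(si) == 0:
            results.append(_skip(name, grouping, "empty or all-unknown stratum"))
        else:
            results.append(_mwu_auto(di, si, name, grouping))
    sub = sno[sno["promoter_type"].isin(["DI", "SI"])]
    if has_te and has_ue and len(sub):
        results.append(_fisher_auto(
            _crosstab(sub, "abundance_class", "promoter_type", classes,
                      ["DI", "SI"]),
            "promoter_vs_class", "UE/TE x DI/SI"))
    else:
        results.append(_skip("promoter_vs_class", "UE/TE x DI/SI",
                             "empty class or all-unknown promoter"))

    # (h) NMD x promoter type, per abundance class
    for cls in classes:
        name = "nmd_vs_promoter"
        grouping = f"{cls}, NMD x DI/SI"
        sub = sno[(sno["abundance_class"] == cls)
                  & sno["promoter_type"].isin(["DI", "SI"])
                  & sno["nmd_substrate"].notna()]
        if len(sub) == 0:
            results.append(_skip(name, grouping, "empty or all-unknown stratum"))
            continue
        sub = sub.assign(nmd=sub["nmd_substrate"].astype(bool))
        results.append(_fisher_auto(
            _crosstab(sub, "nmd", "promoter_type", [True, False], ["DI", "SI"]),
            name, grouping))

    # (i) conservation between correlation classes (anticorrelated vs rest)
    name = "conservation_vs_correlation_class"
    if "conservation_vertebrates" in corr.columns and len(corr):
        anti = corr.loc[corr["correlation_class"] == "anticorrelated",
                        "conservation_vertebrates"]
        rest = corr.loc[corr["correlation_class"] != "anticorrelated",
                        "conservation_vertebrates"]
        results.append(_mwu_auto(anti, rest, name, "anticorrelated vs rest"))
    else:
        results.append(_skip(name, "anticorrelated vs rest", "no data"))

    # (j) snoRNA/host abundance ratio between correlation classes
    if ratios is not None and len(ratios):
        mean_ratio = (ratios.groupby("sno_gene_id")["log2_ratio"].mean()
                      .rename("mean_log2_ratio"))
        rsub = corr.merge(mean_ratio, left_on="sno_gene_id", right_index=True)
        anti = rsub.loc[rsub["correlation_class"] == "anticorrelated",
                        "mean_log2_ratio"]
        for other in ("non-correlated", "positive"):
            name = "ratio_vs_correlation_class"
            grouping = f"anticorrelated vs {other}"
            oth = rsub.loc[rsub["correlation_class"] == other, "mean_log2_ratio"]
            if len(anti) == 0 or len(oth) == 0:
                results.append(_skip(name, grouping, "empty correlation class"))
            else:
                results.append(_mwu_auto(anti, oth, name, grouping))
    return results


def battery_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate battery results (one row per test) for TSV/JSON export."""
    return pd.DataFrame([{
        "test": r.test, "grouping": r.grouping, "statistic": r.statistic,
        "p": r.p, "stars": r.stars, "n": r.n, "status": r.status,
    } for r in results])
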