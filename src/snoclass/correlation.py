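"""snoRNA / host-gene abundance correlation with FDR control.

Intron-embedded snoRNAs are paired with their host gene and the Pearson
correlation of their abundances is computed across observations (the
individual samples by default, or per-tissue means).  Raw p-values are
adjusted with the Benjamini-Hochberg step-up procedure over the family of
all pairs tested in a run, and each pair is assigned a correlation class:
anticorrelated (r < -0.25), non-correlated (-0.25 <= r <= 0.25) or
positively correlated (r > 0.25).  Per-tissue log2 snoRNA-to-host abundance
ratios are also provided for abundance comparisons between classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .data import AbundanceMatrix, TissueProfile, tissue_means
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

#: Default correlation-class cut-offs (lower, upper).
DEFAULT_CUTOFFS = (-0.25, 0.25)


def pair_snorna_host(annotation: pd.DataFrame) -> pd.DataFrame:
    """One (snoRNA, host) pair per intron-embedded snoRNA.

    Intergenic snoRNAs have no host and are excluded with a logged count.
    Two snoRNAs sharing a host yield two pairs.
    """
    sno = annotation[annotation["biotype_group"] == "snoRNA"]
    host = sno.get("host_gene_id", pd.Series("", index=sno.index)).fillna("")
    intronic = host != ""
    n_intergenic = int((~intronic).sum())
    if n_intergenic:
        log.info("stage=pairing action=skip_intergenic count=%d", n_intergenic)
    return pd.DataFrame({
        "sno_gene_id": sno.index[intronic],
        "host_gene_id": host[intronic].values,
    }).reset_index(drop=True)


def correlate_pairs(
    pairs: pd.DataFrame,
    matrix: AbundanceMatrix,
    level: str = "samples",
    log2: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pearson r and two-sided p for each snoRNA/host pair.

    ``level`` selects the observation unit: every individual sample
    (default) or per-tissue replicate means.  With ``log2=True`` the test
    runs on ``log2(TPM + pseudocount)``, the scale on which abundance
    effects are usually multiplicative.  Pairs with a gene absent from the
    matrix, fewer than 3 observations, or zero variance in either series
    are dropped with logged counts before any FDR adjustment.
    """
    if level == "samples":
        table = matrix.values
    elif level == "tissue-means":
        table = tissue_means(matrix).values
    else:
        raise ConfigError(f"unknown correlation level {level!r}")
    if table.shape[1] < 3:
        raise DataError("need at least 3 observations for Pearson correlation")

    records = []
    n_missing = n_flat = 0
    for sno, host in pairs[["sno_gene_id", "host_gene_id"]].itertuples(index=False):
        if sno not in table.index or host not in table.index:
            n_missing += 1
            continue
        x = table.loc[sno].to_numpy(dtype=float)
        y = table.loc[host].to_numpy(dtype=float)
        if log2:
            x = np.log2(x + pseudocount)
            y = np.log2(y + pseudocount)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_flat += 1
            continue
        r, p = pearsonr(x, y)
        records.append({
            "sno_gene_id": sno, "host_gene_id": host,
            "r": float(r), "p_raw": float(p), "n_observations": len(x),
        })
    if n_missing:
        log.warning("stage=correlation action=drop_missing_gene count=%d", n_missing)
    if n_flat:
        log.warning("stage=correlation action=drop_zero_variance count=%d", n_flat)
    return pd.DataFrame(
        records,
        columns=["sno_gene_id", "host_gene_id", "r", "p_raw", "n_observations"],
    )


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_correlation(
    r: float, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> str:
    """Map Pearson's r to anticorrelated / non-correlated / positive.

    The middle band is inclusive on both cut-offs.
    """
    lo, hi = cutoffs
    if not -1 <= r <= 1:
        raise DataError(f"Pearson r outside [-1, 1]: {r}")
    if r < lo:
        return "anticorrelated"
    if r > hi:
        return "positive"
    return "non-correlated"


def finalize_correlations(
    records: pd.DataFrame,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attach BH q-values, correlation classes and a significance flag."""
    out = records.copy()
    if len(out) == 0:
        out["q"] = []
        out["correlation_class"] = []
        out["significant"] = []
        return out
    out["q"] = adjust_fdr(out["p_raw"].to_numpy())
    out["correlation_class"] = [classify_correlation(r, cutoffs) for r in out["r"]]
    out["significant"] = out["q"] < alpha
    return out


def abundance_ratio(
    pairs: pd.DataFrame,
    profile: TissueProfile,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-pair, per-tissue ``log2((sno + pc) / (host + pc))`` ratios."""
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    rows = []
    for sno, host in pairs[["sno_gene_id", "host_gene_id"]].itertuples(index=False):
        if sno not in profile.values.index or host not in profile.values.index:
            continue
        s = profile.values.loc[sno]
        h = profile.values.loc[host]
        for tissue in profile.tissues:
            rows.append({
                "sno_gene_id": sno, "host_gene_id": host, "tissue": tissue,
                "log2_ratio": float(np.log2((s[tissue] + pseudocount)
                                            / (h[tissue] + pseudocount))),
            })
    return pd.DataFrame(
        rows, columns=["sno_gene_id", "host_gene_id", "tissue", "log2_ratio"])
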