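"""Synthetic tissue cohorts with known ground truth.

Generates abundance matrices and annotation tables that emulate the
statistical structure of a seven-tissue, three-replicate snoRNA profiling
experiment: a log-normal baseline of gene abundances, per-tissue biological
jitter calibrated so the CV distribution of uniformly expressed genes modes
near 65, a minority of tissue-enriched genes whose CVs mode above 200
through a 5-50x fold boost in one tissue (or a designated joint tissue
pair), replicate noise, host genes whose log-abundance tracks the snoRNA's
at a planted Pearson correlation, and categorical annotations (box type,
target, host biotype, NMD, promoter type) drawn from a configurable
odds-ratio design between the two abundance classes.  Every simulated gene
carries its ground truth so recovery of classes, correlations and odds
ratios can be tested end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AbundanceMatrix, read_abundance_table, read_annotation
from .errors import ConfigError

TISSUES = ("breast", "ovary", "prostate", "testis",
           "skeletal_muscle", "liver", "brain")


@dataclass(frozen=True)
class FlagDesign:
    """Binary annotation flag with a planted class association.

    ``p_ue`` is the flag probability among UE genes; the flag's odds in the
    TE class are ``odds_ratio`` times the UE odds.
    """

    p_ue: float
    odds_ratio: float

    @property
    def p_te(self) -> float:
        odds = self.p_ue / (1 - self.p_ue) * self.odds_ratio
        return odds / (1 + odds)


def _default_flags() -> dict[str, FlagDesign]:
    # Flag rates loosely shaped after the real snoRNome: box C/D dominates
    # both classes but more strongly in TE; orphans dominate TE; UE genes
    # sit mostly in protein-coding hosts with frequent NMD-sensitive
    # transcripts and dual-initiation promoters.
    return {
        "box_cd": FlagDesign(p_ue=0.70, odds_ratio=2.5),
        "target_orphan": FlagDesign(p_ue=0.25, odds_ratio=8.0),
        "host_protein_coding": FlagDesign(p_ue=0.75, odds_ratio=0.2),
        "nmd_substrate": FlagDesign(p_ue=0.35, odds_ratio=0.4),
        "promoter_di": FlagDesign(p_ue=0.60, odds_ratio=0.25),
    }


@dataclass(frozen=True)
class SimulationParams:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the seven-tissue atlas the pipeline targets: 475
    expressed snoRNAs split 390 UE / 85 TE over 7 tissues x 3 replicates,
    ~9% of snoRNAs intergenic, and a host-correlation design of 60% of
    pairs at rho = 0.7, 25% at 0 and 15% at -0.6 (planted on
    log-abundance).
    """

    n_ue: int = 390
    n_te: int = 85
    tissues: tuple[str, ...] = TISSUES
    replicates_per_tissue: int = 3
    log_tpm_mean: float = 3.3       # natural-log TPM location (median ~27 TPM)
    log_tpm_sd: float = 1.1
    tissue_cv: float = 0.65         # biological spread of tissue means
    te_fold_range: tuple[float, float] = (5.0, 50.0)
    replicate_cv: float = 0.15
    intergenic_fraction: float = 42 / 475
    corr_design: tuple[tuple[float, float], ...] = (
        (0.60, 0.7), (0.25, 0.0), (0.15, -0.6))
    flags: dict[str, FlagDesign] = field(default_factory=_default_flags)
    snrna_fraction: float = 0.3     # snRNA share among canonical targets
    conservation_means: tuple[float, float] = (0.55, 0.30)   # UE, TE
    conservation_means_primates: tuple[float, float] = (0.60, 0.40)
    conservation_concentration: float = 6.0
    host_log_tpm_offset: float = -1.5
    joint_pair: tuple[str, str] = ("breast", "ovary")
    joint_pair_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ue + self.n_te < 50:
            raise ConfigError("cohort too small: need n_ue + n_te >= 50")
        fracs = [f for f, _ in self.corr_design]
        if abs(sum(fracs) - 1.0) > 1e-9 or any(f < 0 for f in fracs):
            raise ConfigError("correlation design fractions must be "
                              "non-negative and sum to 1")
        for name in ("tissue_cv", "replicate_cv", "log_tpm_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def null(self) -> "SimulationParams":
        """Variant with every association removed: all flag odds ratios 1,
        all planted correlations 0, identical conservation distributions."""
        flags = {k: FlagDesign(v.p_ue, 1.0) for k, v in self.flags.items()}
        return dataclasses.replace(
            self, flags=flags, corr_design=((1.0, 0.0),),
            conservation_means=(0.5, 0.5),
            conservation_means_primates=(0.5, 0.5))


@dataclass(eq=False)
class SimulatedCohort:
    """A simulated dataset: matrix, annotation, and per-gene ground truth."""

    matrix: AbundanceMatrix
    annotation: pd.DataFrame
    truth: pd.DataFrame
    params: SimulationParams


def _proportional_counts(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder allocation of n items to fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _beta_ab(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1 - mean) * concentration


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Draw one cohort; bit-identical for identical parameters and seed."""
    p = params
    rng = np.random.default_rng(p.seed)
    tissues = list(p.tissues)
    n_t, n_rep = len(tissues), p.replicates_per_tissue
    n_obs = n_t * n_rep
    n = p.n_ue + p.n_te

    gene_ids = [f"SNO_{i:04d}" for i in range(n)]
    classes = np.array(["UE"] * p.n_ue + ["TE"] * p.n_te)
    rng.shuffle(classes)

    sigma_t = np.sqrt(np.log1p(p.tissue_cv ** 2))
    sigma_r = np.sqrt(np.log1p(p.replicate_cv ** 2))

    base = rng.normal(p.log_tpm_mean, p.log_tpm_sd, size=n)
    tissue_dev = rng.normal(0.0, sigma_t, size=(n, n_t))

    planted_tissues: list[tuple[str, ...]] = []
    te_idx = np.flatnonzero(classes == "TE")
    folds = rng.uniform(*p.te_fold_range, size=len(te_idx))
    joint = rng.random(len(te_idx)) < p.joint_pair_fraction
    pair_idx = [tissues.index(t) for t in p.joint_pair]
    for g in range(n):
        planted_tissues.append(())
    for j, g in enumerate(te_idx):
        if joint[j] and len(pair_idx) == 2:
            # second fold within the 2x window of the first
            second = folds[j] * rng.uniform(0.55, 1.0)
            tissue_dev[g, pair_idx[0]] += np.log(folds[j])
            tissue_dev[g, pair_idx[1]] += np.log(second)
            planted_tissues[g] = tuple(sorted(p.joint_pair))
        else:
            t = int(rng.integers(n_t))
            tissue_dev[g, t] += np.log(folds[j])
            planted_tissues[g] = (tissues[t],)

    rep_noise = rng.normal(0.0, sigma_r, size=(n, n_obs))
    log_tpm = (base[:, None]
               + np.repeat(tissue_dev, n_rep, axis=1)
               + rep_noise)
    sno_tpm = np.exp(log_tpm)

    # --- genomic context and hosts -------------------------------------
    n_intergenic = int(round(p.intergenic_fraction * n))
    intergenic = np.zeros(n, dtype=bool)
    intergenic[rng.choice(n, size=n_intergenic, replace=False)] = True
    intronic_idx = np.flatnonzero(~intergenic)

    rho_counts = _proportional_counts(
        len(intronic_idx), [f for f, _ in p.corr_design])
    rho_values = np.concatenate([
        np.full(c, rho) for c, (_, rho) in zip(rho_counts, p.corr_design)])
    rng.shuffle(rho_values)

    sigma_h = np.sqrt(sigma_t ** 2 + sigma_r ** 2)
    host_ids, host_rows, host_tpm_rows = [], [], []
    planted_rho = np.full(n, np.nan)
    for j, g in enumerate(intronic_idx):
        rho = float(rho_values[j])
        planted_rho[g] = rho
        hid = f"HOST_{g:04d}"
        host_ids.append(hid)
        z = log_tpm[g] - log_tpm[g].mean()
        sd = z.std()
        z = z / sd if sd > 0 else np.zeros_like(z)
        w = rng.normal(0.0, 1.0, size=n_obs)
        mu_h = rng.normal(p.log_tpm_mean + p.host_log_tpm_offset, p.log_tpm_sd)
        host_log = mu_h + sigma_h * (rho * z + np.sqrt(1 - rho ** 2) * w)
        host_tpm_rows.append(np.exp(host_log))
        host_rows.append(g)

    # --- categorical annotation flags ----------------------------------
    is_te = classes == "TE"

    def draw_flag(name: str) -> np.ndarray:
        d = p.flags[name]
        prob = np.where(is_te, d.p_te, d.p_ue)
        return rng.random(n) < prob

    box_cd = draw_flag("box_cd")
    orphan = draw_flag("target_orphan")
    host_pc = draw_flag("host_protein_coding")
    nmd = draw_flag("nmd_substrate")
    di = draw_flag("promoter_di")
    snrna_target = rng.random(n) < p.snrna_fraction

    func_groups = np.array(["ribosomal protein",
                            "RNA processing / ribosome biogenesis",
                            "other", "unknown"])
    host_func = func_groups[rng.choice(4, size=n, p=[0.3, 0.3, 0.3, 0.1])]

    cons_ue_v = _beta_ab(p.conservation_means[0], p.conservation_concentration)
    cons_te_v = _beta_ab(p.conservation_means[1], p.conservation_concentration)
    cons_ue_p = _beta_ab(p.conservation_means_primates[0],
                         p.conservation_concentration)
    cons_te_p = _beta_ab(p.conservation_means_primates[1],
                         p.conservation_concentration)
    cons_v = np.where(is_te, rng.beta(*cons_te_v, size=n),
                      rng.beta(*cons_ue_v, size=n))
    cons_p = np.where(is_te, rng.beta(*cons_te_p, size=n),
                      rng.beta(*cons_ue_p, size=n))

    # --- assemble tables ------------------------------------------------
    sample_ids = [f"{t}_{r + 1}" for t in tissues for r in range(n_rep)]
    sample_to_tissue = pd.Series(
        [t for t in tissues for _ in range(n_rep)], index=sample_ids,
        name="tissue")

    all_ids = gene_ids + host_ids
    values = pd.DataFrame(
        np.vstack([sno_tpm, np.vstack(host_tpm_rows)]) if host_ids
        else sno_tpm,
        index=all_ids, columns=sample_ids)
    matrix = AbundanceMatrix(values, sample_to_tissue)

    host_of = {g: h for g, h in zip(host_rows, host_ids)}
    ann_rows = []
    for g, gid in enumerate(gene_ids):
        hid = host_of.get(g, "")
        ann_rows.append({
            "gene_id": gid,
            "gene_name": gid,
            "biotype_raw": "snoRNA",
            "biotype_group": "snoRNA",
            "genomic_context": "intergenic" if intergenic[g] else "intronic",
            "host_gene_id": hid,
            "host_biotype_group": ("intergenic" if intergenic[g] else
                                   ("protein-coding" if host_pc[g]
                                    else "non-coding")),
            "host_function_group": ("" if intergenic[g] or not host_pc[g]
                                    else host_func[g]),
            "box_type": "CD" if box_cd[g] else "HACA",
            "target_class": ("orphan" if orphan[g] else
                             ("snRNA" if snrna_target[g] else "rRNA")),
            "nmd_substrate": "" if intergenic[g] else str(bool(nmd[g])),
            "promoter_type": ("unknown" if intergenic[g]
                              else ("DI" if di[g] else "SI")),
            "conservation_vertebrates": float(cons_v[g]),
            "conservation_primates": float(cons_p[g]),
        })
    for g, hid in zip(host_rows, host_ids):
        ann_rows.append({
            "gene_id": hid,
            "gene_name": hid,
            "biotype_raw": "protein_coding" if host_pc[g] else "lincRNA",
            "biotype_group": ("protein-coding" if host_pc[g] else "lncRNA"),
            "genomic_context": "intergenic",
            "host_gene_id": "",
            "host_biotype_group": "intergenic",
            "host_function_group": "",
            "box_type": "NA",
            "target_class": "NA",
            "nmd_substrate": "",
            "promoter_type": "unknown",
            "conservation_vertebrates": np.nan,
            "conservation_primates": np.nan,
        })
    annotation = pd.DataFrame(ann_rows).set_index("gene_id")
    annotation["nmd_substrate"] = (annotation["nmd_substrate"]
                                   .map({"True": True, "False": False})
                                   .astype("boolean"))

    truth_rows = []
    for g, gid in enumerate(gene_ids):
        truth_rows.append({
            "gene_id": gid,
            "planted_class": classes[g],
            "planted_tissues": ";".join(planted_tissues[g]),
            "planted_rho": planted_rho[g],
            "box_cd": bool(box_cd[g]),
            "target_orphan": bool(orphan[g]),
            "host_protein_coding": (bool(host_pc[g])
                                    if not intergenic[g] else None),
            "nmd_substrate": bool(nmd[g]) if not intergenic[g] else None,
            "promoter_di": bool(di[g]) if not intergenic[g] else None,
        })
    for hid in host_ids:
        truth_rows.append({
            "gene_id": hid, "planted_class": "host", "planted_tissues": "",
            "planted_rho": np.nan, "box_cd": None, "target_orphan": None,
            "host_protein_coding": None, "nmd_substrate": None,
            "promoter_di": None,
        })
    truth = pd.DataFrame(truth_rows).set_index("gene_id")

    return SimulatedCohort(matrix=matrix, annotation=annotation,
                           truth=truth, params=p)


def write_fixture(cohort: SimulatedCohort, directory) -> dict[str, Path]:
    """Write a cohort as plain TSV files readable by the data layer."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": d / "abundance.tsv",
        "samples": d / "samples.tsv",
        "annotation": d / "annotation.tsv",
        "truth": d / "truth.tsv",
        "params": d / "params.json",
    }
    m = cohort.matrix
    m.values.rename_axis("gene_id").to_csv(paths["abundance"], sep="\t")
    (m.sample_to_tissue.rename_axis("sample").rename("tissue")
     .to_frame().to_csv(paths["samples"], sep="\t"))
    cohort.annotation.rename_axis("gene_id").to_csv(paths["annotation"], sep="\t")
    cohort.truth.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")
    pdict = dataclasses.asdict(cohort.params)
    pdict["flags"] = {k: dataclasses.asdict(v)
                      for k, v in cohort.params.flags.items()}
    paths["params"].write_text(json.dumps(pdict, indent=2, default=list))
    return paths


def read_fixture(directory) -> tuple[AbundanceMatrix, pd.DataFrame, pd.DataFrame]:
    """Read back a written fixture: (matrix, annotation, truth)."""
    d = Path(directory)
    matrix = read_abundance_table(d / "abundance.tsv", d / "samples.tsv")
    annotation = read_annotation(d / "annotation.tsv")
    truth = pd.read_csv(d / "truth.tsv", sep="\t", index_col=0,
                        keep_default_na=True)
    return matrix, annotation, truth
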