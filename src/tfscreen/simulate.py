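"""Synthetic inputs with planted ground truth for every screening stage.

Every generator derives its own random substream from the master seed and a
fixed per-generator key, so a given :class:`SimConfig` always produces
byte-identical outputs and adding one generator never perturbs another.

Default sizes mirror the screen's real design: 702 TF genes tested across
15 expression cohorts, a 117-gene signature set against 1500 control
promoters, a 345-motif library, 2 kb promoters, triplicate protein/DNA
arrays over 4 + 4 cell lines, and survival cohorts with a true marker
hazard ratio of 1.42.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import log, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .promoters import PromoterSet, extract_promoters
from .pwm import BASES, PWMatrix
from .rna_screen import ExpressionCohort

# fixed substream keys: one per generator
_STREAMS = {
    "expression": 1,
    "signature": 2,
    "pwms": 3,
    "promoters": 4,
    "array": 5,
    "growth": 6,
    "survival": 7,
    "truth": 8,
}


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic screen; defaults follow the study design."""

    seed: int = 0
    n_cohorts: int = 15
    n_genes: int = 2000
    n_tf_genes: int = 702
    n_samples_per_group: int = 30
    cohort_sizes: list[int] | None = None  # per-cohort n/group, overrides above
    effect_size: float = 1.0  # standardized mean shift of planted DE TFs
    n_planted_de: int = 25
    dropout_fraction: float = 0.0  # genes missing per cohort (platform thinning)
    promoter_length: int = 2000  # 1000 upstream + exon 1
    n_target_genes: int = 117
    n_control_genes: int = 1500
    n_motifs: int = 345
    motif_length: int = 8
    motif_plant_rate: float = 0.5
    control_plant_rate: float = 0.0
    gc_content: float = 0.5
    array_fc: float = 2.0  # true group fold change of bound motifs
    array_cv: float = 0.15  # spot noise coefficient of variation
    growth_noise_sd: float = 10.0  # percent-growth SD
    surv_betas: dict[str, float] = field(
        default_factory=lambda: {"marker": log(1.42)}
    )
    censor_rate: float = 0.3
    n_subjects: int = 2000

    def __post_init__(self) -> None:
        if self.n_planted_de > self.n_tf_genes:
            raise ConfigError("n_planted_de exceeds n_tf_genes")
        if self.n_tf_genes > self.n_genes:
            raise ConfigError("n_tf_genes exceeds n_genes")
        for fld in ("motif_plant_rate", "control_plant_rate", "gc_content",
                    "dropout_fraction", "censor_rate"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{fld} must be in [0, 1], got {v}")
        for fld in ("n_cohorts", "n_genes", "n_samples_per_group", "n_motifs",
                    "promoter_length", "motif_length", "n_subjects"):
            if getattr(self, fld) < 1:
                raise ConfigError(f"{fld} must be >= 1")
        if self.n_samples_per_group < 2:
            raise ConfigError("n_samples_per_group must be >= 2")
        if self.array_cv < 0:
            raise ConfigError("array_cv must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, for recovery tests."""

    de_tfs: list[str] = field(default_factory=list)
    planted_motifs: dict[str, str] = field(default_factory=dict)  # motif -> TF gene
    bound_motifs: list[str] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)
    critical_tfs: list[str] = field(default_factory=list)
    true_surv_coefs: dict[str, float] = field(default_factory=dict)
    plant_positions: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


def gene_ids(cfg: SimConfig) -> tuple[list[str], list[str]]:
    """All gene ids and the TF-whitelist subset (TF genes come first)."""
    tfs = [f"TF{i:04d}" for i in range(1, cfg.n_tf_genes + 1)]
    others = [f"G{i:04d}" for i in range(1, cfg.n_genes - cfg.n_tf_genes + 1)]
    return tfs + others, tfs


def pick_planted_tfs(cfg: SimConfig) -> list[str]:
    _, tfs = gene_ids(cfg)
    rng = cfg.rng("truth")
    return sorted(map(str, rng.choice(tfs, size=cfg.n_planted_de, replace=False)))


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

def gen_expression_cohorts(
    cfg: SimConfig,
    planted: list[str] | None = None,
) -> tuple[list[ExpressionCohort], PlantedTruth]:
    """Cohorts of log-expression with planted case-elevated TF genes.

    Planted genes are shifted upward by ``effect_size`` (in noise-SD units)
    in the case group of every cohort; all other genes are pure noise.  With
    ``dropout_fraction`` > 0 each cohort measures only a random gene subset,
    emulating platform differences.
    """
    genes, _ = gene_ids(cfg)
    if planted is None:
        planted = pick_planted_tfs(cfg) if cfg.effect_size != 0 else []
    unknown = set(planted) - set(genes)
    if unknown:
        raise ConfigError(f"planted genes not in gene universe: {sorted(unknown)}")
    rng = cfg.rng("expression")
    sizes = cfg.cohort_sizes or [cfg.n_samples_per_group] * cfg.n_cohorts
    if len(sizes) != cfg.n_cohorts:
        raise ConfigError("cohort_sizes length must equal n_cohorts")
    planted_mask = np.isin(np.array(genes), planted)
    cohorts = []
    for c, n in enumerate(sizes, start=1):
        keep = np.ones(len(genes), dtype=bool)
        if cfg.dropout_fraction > 0:
            keep = rng.random(len(genes)) >= cfg.dropout_fraction
        idx = [g for g, k in zip(genes, keep) if k]
        values = rng.standard_normal((len(idx), 2 * n))
        values[planted_mask[keep], :n] += cfg.effect_size
        samples = [f"C{c:02d}S{j:03d}" for j in range(1, 2 * n + 1)]
        group = pd.Series([1] * n + [0] * n, index=samples)
        cohorts.append(
            ExpressionCohort(
                cohort_id=f"cohort{c:02d}",
                values=pd.DataFrame(values, index=idx, columns=samples),
                group=group,
            )
        )
    truth = PlantedTruth(de_tfs=sorted(planted))
    return cohorts, truth


def gen_signature_cohorts(
    cfg: SimConfig,
    target_genes: list[str],
    n_cohorts: int = 3,
    effect_size: float = 2.5,
) -> list[ExpressionCohort]:
    """Subtype cohorts in which the target (signature) genes are elevated.

    These feed the signature-gene-set derivation: each target gene is
    case-elevated in every cohort, so the per-cohort p<0.01 intersection
    recovers the planted set.
    """
    genes, _ = gene_ids(cfg)
    rng = cfg.rng("signature")
    mask = np.isin(np.array(genes), target_genes)
    n = cfg.n_samples_per_group
    cohorts = []
    for c in range(1, n_cohorts + 1):
        values = rng.standard_normal((len(genes), 2 * n))
        values[mask, :n] += effect_size
        samples = [f"B{c}S{j:03d}" for j in range(1, 2 * n + 1)]
        cohorts.append(
            ExpressionCohort(
                cohort_id=f"subtype{c}",
                values=pd.DataFrame(values, index=genes, columns=samples),
                group=pd.Series([1] * n + [0] * n, index=samples),
            )
        )
    return cohorts


# ---------------------------------------------------------------------------
# PWM library and promoters
# ---------------------------------------------------------------------------

def gen_pwm_library(cfg: SimConfig) -> tuple[list[PWMatrix], dict[str, set[str]]]:
    """Synthetic motif library plus a motif -> TF-gene annotation map.

    Each motif is an information-rich count matrix (a dominant base per
    position with minority counts), annotated to one TF-whitelist gene in
    round-robin order so every planted TF owns at least one motif.
    """
    _, tfs = gene_ids(cfg)
    rng = cfg.rng("pwms")
    pwms, mapping = [], {}
    for i in range(cfg.n_motifs):
        motif_id = f"M{i + 1:03d}"
        dominant = rng.integers(0, 4, size=cfg.motif_length)
        counts = rng.integers(0, 4, size=(cfg.motif_length, 4)).astype(float)
        counts[np.arange(cfg.motif_length), dominant] += rng.integers(12, 20)
        pwms.append(PWMatrix(motif_id=motif_id, counts=counts))
        mapping[motif_id] = {tfs[i % len(tfs)]}
    return pwms, mapping


def sample_site(pwm: PWMatrix, rng: np.random.Generator) -> str:
    """One binding site drawn position-wise from the PWM frequencies."""
    return "".join(
        BASES[rng.choice(4, p=pwm.freqs[i])] for i in range(len(pwm))
    )


def gen_promoters(
    cfg: SimConfig,
    pwm_library: list[PWMatrix],
    target_genes: list[str],
    control_genes: list[str],
    planted_motifs: list[str] | None = None,
    plant_consensus: bool = False,
) -> tuple[dict[str, str], pd.DataFrame, PromoterSet, PlantedTruth]:
    """Synthetic genome, gene table and promoters with planted motif sites.

    Background sequence is i.i.d. with the configured GC content.  For each
    planted motif, a site sampled from its PWM (or the exact consensus when
    ``plant_consensus``) is written at a random position into
    ``motif_plant_rate`` of the target promoters (and at
    ``control_plant_rate`` of controls).  The per-gene randomness (plant
    decision, site, position) is drawn whether or not the site is inserted,
    so runs at different plant rates under the same seed are coupled
    monotonically.  Returns the genome (one contig per gene), a
    1-based-inclusive gene table, the promoter set as built, and the planted
    truth with recorded insertion offsets.
    """
    if not pwm_library:
        raise ConfigError("pwm_library is empty")
    overlap = set(target_genes) & set(control_genes)
    if overlap:
        raise ConfigError(f"target/control gene sets overlap: {sorted(overlap)[:5]}")
    by_id = {p.motif_id: p for p in pwm_library}
    planted_motifs = list(planted_motifs or [])
    longest = max(len(p) for p in pwm_library)
    if cfg.promoter_length < longest:
        raise ConfigError(
            f"promoter_length {cfg.promoter_length} shorter than longest motif {longest}"
        )
    rng = cfg.rng("promoters")
    base_p = np.array(
        [(1 - cfg.gc_content) / 2, cfg.gc_content / 2, cfg.gc_content / 2,
         (1 - cfg.gc_content) / 2]
    )
    upstream = min(1000, cfg.promoter_length - 1)
    exon1_len = cfg.promoter_length - upstream

    genome: dict[str, str] = {}
    rows = []
    promoters: dict[str, str] = {}
    positions: dict[str, list[int]] = {}
    flank = 25

    for gene in list(target_genes) + list(control_genes):
        is_target = gene in set(target_genes)
        seq = rng.choice(4, size=cfg.promoter_length, p=base_p)
        seq = "".join(BASES[b] for b in seq)
        for mid in planted_motifs:
            pwm = by_id[mid]
            rate = cfg.motif_plant_rate if is_target else cfg.control_plant_rate
            u = rng.random()
            site = pwm.consensus if plant_consensus else sample_site(pwm, rng)
            pos = int(rng.integers(0, cfg.promoter_length - len(pwm) + 1))
            if u < rate:
                seq = seq[:pos] + site + seq[pos + len(pwm):]
                positions.setdefault(gene, []).append(pos + 1)
        promoters[gene] = seq
        strand = "+" if rng.random() < 0.5 else "-"
        flanks = "".join(BASES[b] for b in rng.choice(4, size=2 * flank, p=base_p))
        if strand == "+":
            contig = flanks[:flank] + seq + flanks[flank:]
            tss = flank + upstream + 1  # 1-based
            exon1_end = tss + exon1_len - 1
        else:
            from .pwm import reverse_complement

            contig = flanks[:flank] + reverse_complement(seq) + flanks[flank:]
            tss = flank + exon1_len  # 1-based position of TSS on forward strand
            exon1_end = tss - exon1_len + 1
        chrom = f"chr_{gene}"
        genome[chrom] = contig
        rows.append(
            {"gene": gene, "chrom": chrom, "strand": strand,
             "tss": tss, "exon1_end": exon1_end}
        )

    gene_table = pd.DataFrame(rows)
    truth = PlantedTruth(
        planted_motifs={m: "" for m in planted_motifs},
        target_genes=sorted(target_genes),
        plant_positions=positions,
    )
    return genome, gene_table, PromoterSet(promoters, provenance="synthetic"), truth


# ---------------------------------------------------------------------------
# protein/DNA array
# ---------------------------------------------------------------------------

BLBC_LINES = ["HCC1143", "HCC1937", "BT20", "MDA468"]
LUMINAL_LINES = ["T47D", "MCF7", "BT474", "ZR751"]
ARRAY_GROUP_MAP = {**{l: "BLBC" for l in BLBC_LINES},
                   **{l: "non-BLBC" for l in LUMINAL_LINES}}


def gen_array_intensities(
    cfg: SimConfig,
    motif_ids: list[str],
    bound_motifs: list[str] | None = None,
    cell_lines: dict[str, str] | None = None,
    n_replicates: int = 3,
    reference_id: str = "TFIID",
) -> pd.DataFrame:
    """Spot-intensity long table with planted group fold changes.

    Bound motifs have a true BLBC/non-BLBC mean ratio of ``array_fc``;
    all spots (including the reference) carry multiplicative log-normal
    noise with coefficient of variation ``array_cv``, and each membrane has
    its own overall scale (removed downstream by reference normalisation).
    """
    import warnings as _warnings

    group_map = cell_lines or ARRAY_GROUP_MAP
    bound = set(bound_motifs or [])
    motif_ids = list(motif_ids)
    if reference_id not in motif_ids:
        _warnings.warn(f"reference spot {reference_id} auto-added", stacklevel=2)
        motif_ids = motif_ids + [reference_id]
    rng = cfg.rng("array")
    sigma = sqrt(log(1.0 + cfg.array_cv**2)) if cfg.array_cv > 0 else 0.0
    base = {m: float(rng.lognormal(log(100.0), 0.5)) for m in motif_ids
            if m != reference_id}
    base[reference_id] = 500.0
    rows = []
    for line in group_map:
        is_case = group_map[line] == "BLBC"
        for rep in range(1, n_replicates + 1):
            membrane = f"{line}_r{rep}"
            scale = float(rng.lognormal(0.0, 0.2))
            for m in motif_ids:
                level = base[m] * scale
                if m in bound and is_case:
                    level *= cfg.array_fc
                noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
                rows.append(
                    {"membrane": membrane, "cell_line": line, "replicate": rep,
                     "motif_id": m, "intensity": level * noise}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# growth screen
# ---------------------------------------------------------------------------

GROWTH_BLBC = ["BT20", "HCC1143", "MDA468"]
GROWTH_NONBLBC = ["MCF7", "T47D", "ZR751"]
GROWTH_GROUP_MAP = {**{l: "BLBC" for l in GROWTH_BLBC},
                    **{l: "non-BLBC" for l in GROWTH_NONBLBC}}


def gen_growth_table(
    cfg: SimConfig,
    tfs: list[str],
    critical_tfs: list[str] | None = None,
    pattern: dict[str, dict[str, float]] | None = None,
    group_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Relative-growth table (percent of non-targeting control) per siRNA x line.

    Planted critical TFs get suppressed means (50%) in all BLBC lines and
    near-normal growth (95%) elsewhere, unless an explicit per-line
    ``pattern`` overrides; all cells get Gaussian noise with
    ``growth_noise_sd``, floored at 0.
    """
    group_map = group_map or GROWTH_GROUP_MAP
    critical = list(critical_tfs or [])
    rng = cfg.rng("growth")
    rows = []
    for tf in tfs:
        for line, grp in group_map.items():
            if pattern and tf in pattern and line in pattern[tf]:
                mean = pattern[tf][line]
            elif tf in critical and grp == "BLBC":
                mean = 50.0
            elif tf in critical:
                mean = 95.0
            else:
                mean = 100.0
            noisy = mean + (rng.normal(0.0, cfg.growth_noise_sd)
                            if cfg.growth_noise_sd > 0 else 0.0)
            rows.append(
                {"siRNA": tf, "cell_line": line,
                 "mean": max(noisy, 0.0), "sd": cfg.growth_noise_sd}
            )
    truth = PlantedTruth(critical_tfs=sorted(critical))
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def gen_survival_cohort(
    cfg: SimConfig,
    n: int | None = None,
    baseline_rate: float = 0.1,
    continuous_marker: bool = False,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Exponential proportional-hazards cohort with independent censoring.

    Each covariate in ``surv_betas`` is Bernoulli(1/2); event times are
    exponential with rate ``baseline_rate * exp(sum beta_j x_j)``.
    Censoring times are exponential with a rate solved numerically so the
    expected censored fraction equals ``censor_rate`` — censoring stays
    independent of the event time given covariates, as the Cox model
    assumes.

    With ``continuous_marker`` the ``marker`` column holds a continuous
    expression level (standard normal) and its hazard coefficient acts on
    the high/low indicator at the population median, emulating a
    dichotomized expression marker.
    """
    if cfg.censor_rate < 0:
        raise ConfigError("censor_rate must be non-negative")
    n = n or cfg.n_subjects
    rng = cfg.rng("survival")
    covs = {name: rng.integers(0, 2, size=n).astype(float)
            for name in cfg.surv_betas}
    hazard_covs = dict(covs)
    if continuous_marker and "marker" in covs:
        expression = rng.standard_normal(n)
        covs["marker"] = expression
        hazard_covs["marker"] = (expression > 0).astype(float)
    lp = sum(beta * hazard_covs[name] for name, beta in cfg.surv_betas.items())
    rates = baseline_rate * np.exp(lp if isinstance(lp, np.ndarray) else np.zeros(n))
    t_event = rng.exponential(1.0 / rates)
    if cfg.censor_rate == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        def expected_censored(c):
            return float(np.mean(c / (c + rates))) - cfg.censor_rate

        c_rate = brentq(expected_censored, 1e-9, 1e6)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    df = pd.DataFrame({"time": time, "event": event, **covs})
    truth = PlantedTruth(true_surv_coefs=dict(cfg.surv_betas))
    return df, truth


# ---------------------------------------------------------------------------
# coordinated full-screen simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenData:
    """Every input of the integrated screen, generated coherently."""

    cfg: SimConfig
    cohorts: list[ExpressionCohort]
    signature_cohorts: list[ExpressionCohort]
    tf_whitelist: list[str]
    pwms: list[PWMatrix]
    motif_gene_map: dict[str, set[str]]
    genome: dict[str, str]
    gene_table: pd.DataFrame
    promoters: PromoterSet
    array_intensities: pd.DataFrame
    array_group_map: dict[str, str]
    growth_table: pd.DataFrame
    growth_group_map: dict[str, str]
    survival: pd.DataFrame
    truth: PlantedTruth


def simulate_screen(cfg: SimConfig) -> ScreenData:
    """Generate all screen inputs with one coherent planted truth.

    The planted TF genes are simultaneously (i) case-elevated in every
    expression cohort, (ii) owners of motifs planted into the signature-gene
    promoters, and (iii) owners of motifs bound more strongly on the BLBC
    arrays — so each planted TF is recoverable by all three assays and the
    >=2-of-3 integration.
    """
    genes, tfs = gene_ids(cfg)
    planted = pick_planted_tfs(cfg) if cfg.effect_size != 0 else []
    cohorts, truth = gen_expression_cohorts(cfg, planted=planted)

    pwms, mapping = gen_pwm_library(cfg)
    # remap one motif to each planted TF so DNA/protein hits translate to them
    motif_of: dict[str, str] = {}
    tf_rank = {tf: i for i, tf in enumerate(tfs)}
    for j, tf in enumerate(sorted(planted, key=tf_rank.get)):
        mid = pwms[j % len(pwms)].motif_id
        mapping[mid] = {tf}
        motif_of[tf] = mid
    planted_motifs = sorted(set(motif_of.values()))

    rng = cfg.rng("truth")
    non_tf = [g for g in genes if g not in set(tfs)]
    target_genes = sorted(map(str, rng.choice(non_tf, size=cfg.n_target_genes, replace=False)))
    sig_cohorts = gen_signature_cohorts(cfg, target_genes)
    control_pool = sorted(set(non_tf) - set(target_genes))
    n_ctrl = min(cfg.n_control_genes, len(control_pool))
    control_genes = sorted(map(str, rng.choice(control_pool, size=n_ctrl, replace=False)))

    genome, gene_table, promoters, ptruth = gen_promoters(
        cfg, pwms, target_genes, control_genes, planted_motifs
    )

    array = gen_array_intensities(
        cfg, [p.motif_id for p in pwms], bound_motifs=planted_motifs
    )
    growth, gtruth = gen_growth_table(cfg, tfs=sorted(planted),
                                      critical_tfs=sorted(planted))
    surv, struth = gen_survival_cohort(cfg)

    truth.planted_motifs = {m: tf for tf, m in motif_of.items()}
    truth.bound_motifs = planted_motifs
    truth.target_genes = target_genes
    truth.plant_positions = ptruth.plant_positions
    truth.critical_tfs = gtruth.critical_tfs
    truth.true_surv_coefs = struth.true_surv_coefs

    return ScreenData(
        cfg=cfg,
        cohorts=cohorts,
        signature_cohorts=sig_cohorts,
        tf_whitelist=tfs,
        pwms=pwms,
        motif_gene_map=mapping,
        genome=genome,
        gene_table=gene_table,
        promoters=promoters,
        array_intensities=array,
        array_group_map=dict(ARRAY_GROUP_MAP),
        growth_table=growth,
        growth_group_map=dict(GROWTH_GROUP_MAP),
        survival=surv,
        truth=truth,
    )


def desk_config(seed: int = 0, **overrides) -> SimConfig:
    """A small, fast configuration exercising every stage end to end."""
    defaults = dict(
        seed=seed,
        n_cohorts=5,
        n_genes=400,
        n_tf_genes=80,
        n_samples_per_group=30,
        effect_size=2.0,
        n_planted_de=10,
        promoter_length=400,
        n_target_genes=60,
        n_control_genes=200,
        n_motifs=30,
        array_fc=2.0,
        array_cv=0.1,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_cohort_tsv(cohort: ExpressionCohort, values_path, groups_path) -> None:
    cohort.values.rename_axis("gene").to_csv(values_path, sep="\t")
    cohort.group.rename("group").rename_axis("sample").to_csv(groups_path, sep="\t")


def read_cohort_tsv(cohort_id: str, values_path, groups_path) -> ExpressionCohort:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    group = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"]
    return ExpressionCohort(cohort_id=cohort_id, values=values, group=group)


def write_inputs(data: ScreenData, outdir) -> None:
    """Persist every generated input in its interchange format."""
    from .pwm import write_transfac
    from .promoters import write_genome_fasta

    out = Path(outdir)
    (out / "cohorts").mkdir(parents=True, exist_ok=True)
    for c in data.cohorts + data.signature_cohorts:
        write_cohort_tsv(c, out / "cohorts" / f"{c.cohort_id}.tsv",
                         out / "cohorts" / f"{c.cohort_id}.groups.tsv")
    (out / "tf_whitelist.tsv").write_text(
        "gene\n" + "\n".join(data.tf_whitelist) + "\n"
    )
    write_transfac(data.pwms, out / "motifs.transfac")
    pd.DataFrame(
        [(m, g) for m, gs in sorted(data.motif_gene_map.items()) for g in sorted(gs)],
        columns=["motif_id", "gene_symbol"],
    ).to_csv(out / "motif_gene_map.tsv", sep="\t", index=False)
    write_genome_fasta(data.genome, out / "genome.fa")
    data.gene_table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
    data.promoters.to_fasta(out / "promoters.fa")
    data.array_intensities.to_csv(out / "array_intensities.tsv", sep="\t", index=False)
    pd.Series(data.array_group_map, name="group").rename_axis("cell_line").to_csv(
        out / "array_groups.tsv", sep="\t"
    )
    data.growth_table.to_csv(out / "growth_table.tsv", sep="\t", index=False)
    pd.Series(data.growth_group_map, name="group").rename_axis("cell_line").to_csv(
        out / "growth_groups.tsv", sep="\t"
    )
    data.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
    data.truth.to_json(out / "planted_truth.json")
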