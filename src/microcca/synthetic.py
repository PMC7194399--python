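"""Synthetic anaerobic co-digestion 16S datasets with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a small design (5 co-substrate mixture levels x 2 time points),
several hundred OTUs with a dominant/subdominant abundance hierarchy and
high sparsity, OTU groups responding linearly (positively or negatively) or
quadratically (mixture-preferring, peaked at 50 %) to the mixture gradient,
overdispersed negative-binomial counts, and performance markers linearly
coupled to the latent community activity plus Gaussian noise.

Expected relative abundances are a softmax over per-OTU linear predictors

    eta_ij = baseline_j + beta_j * g_i + gamma_j * m_i

with ``g`` the centered mixture gradient and ``m`` the quadratic
mixture-preference latent, which enforces the compositional constraint the
real data acquires after total-sum scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cca import CcaModel, SelectionResult
from .io_formats import (
    RANKS,
    UNKNOWN,
    OtuTable,
    PerformanceTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

# Lineage pools: (domain, phylum, class, order, family, genus).  Archaeal
# genera and bacterial orders typical of mesophilic anaerobic digesters.
ARCHAEA_LINEAGES = [
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanosarcinales", "Methanosarcinaceae", "Methanosarcina"),
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanomicrobiaceae", "Methanoculleus"),
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanomicrobiaceae", "Methanofollis"),
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanocorpusculaceae", "Methanocorpusculum"),
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanospirillaceae", "Methanospirillum"),
    ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobacterium"),
]
BACTERIA_LINEAGES = [
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Christensenellaceae", "Christensenella"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Proteiniphilum"),
    ("Bacteria", "Chloroflexi", "Anaerolineae", "Anaerolineales", "Anaerolineaceae", "Leptolinea"),
    ("Bacteria", "Cloacimonetes", "Cloacimonadia", "Cloacimonadales", "Cloacimonadaceae", "Candidatus_Cloacimonas"),
    ("Bacteria", "Synergistetes", "Synergistia", "Synergistales", "Synergistaceae", "Aminobacterium"),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Bacteria", "Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae", "Treponema"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Betaproteobacteriales", "Rhodocyclaceae", "Azonexus"),
    ("Bacteria", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", "Fibrobacter"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Enterobacter"),
]

GROUPS = ("gradient_pos", "gradient_neg", "mixture_pref", "inactive")


@dataclass
class MarkerCoupling:
    """One performance marker linearly coupled to a latent."""

    name: str
    latent: str  # "gradient" or "mixture"
    slope: float
    noise_sd: float
    intercept: float = 0.0
    unit: str = ""


def default_marker_couplings() -> list[MarkerCoupling]:
    return [
        MarkerCoupling("alpha_app", "gradient", slope=0.4, noise_sd=0.03,
                       intercept=0.55, unit="fraction"),
        MarkerCoupling("nh4", "gradient", slope=-3.0, noise_sd=0.12,
                       intercept=2.5, unit="g N/L"),
        MarkerCoupling("acetate", "mixture", slope=2.0, noise_sd=0.1,
                       intercept=1.0, unit="g/L"),
    ]


@dataclass
class SyntheticScenario:
    """Parameters of one simulated co-digestion experiment.

    Defaults mirror the study design: 5 mixture levels x 2 time points
    (10 samples), 600 OTUs of which most are inactive background, mean
    library size 50 000 reads and strongly overdispersed counts.
    ``effect_size`` is the log-fold span of the gradient response across
    the full 0-100 % range; the quadratic mixture-preference response uses
    ``effect_size * mixture_effect_scale``.
    """

    n_levels: int = 5
    n_timepoints: int = 2
    n_otus: int = 600
    group_sizes: tuple[int, int, int, int] | None = None
    archaea_fraction: float = 0.08
    depth: float = 50_000.0
    depth_cv: float = 0.15
    dispersion: float = 5.0
    effect_size: float = 4.0
    mixture_effect_scale: float = 0.5
    baseline_sd: float = 0.3
    active_baseline_mean: float = 1.0
    inactive_baseline_mean: float = -8.0
    inactive_baseline_sd: float = 1.0
    unclassified_prob: float = 0.15
    cosubstrate: str = "FW"
    marker_couplings: list[MarkerCoupling] = field(default_factory=default_marker_couplings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            gp = round(0.10 * self.n_otus)
            gn = round(0.10 * self.n_otus)
            mp = round(self.n_otus / 15)
            self.group_sizes = (gp, gn, mp, self.n_otus - gp - gn - mp)
        if sum(self.group_sizes) != self.n_otus:
            raise ValidationError(
                f"group sizes {self.group_sizes} do not sum to n_otus={self.n_otus}"
            )
        if min(self.group_sizes) < 0:
            raise ValidationError("group sizes must be non-negative")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")


@dataclass
class SyntheticTruth:
    """Planted structure: group labels, latents and marker parameters."""

    otu_groups: pd.Series      # otu_id -> group label
    gradient: pd.Series        # sample_id -> centered gradient g in [-0.5, 0.5]
    mixture: pd.Series         # sample_id -> mixture-preference latent m in [0, 1]
    marker_couplings: list[MarkerCoupling]

    def gradient_otus(self) -> list[str]:
        mask = self.otu_groups.isin(["gradient_pos", "gradient_neg"])
        return list(self.otu_groups.index[mask])


@dataclass
class SyntheticData:
    otu_table: OtuTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    markers: PerformanceTable
    truth: SyntheticTruth


def generate(scn: SyntheticScenario) -> SyntheticData:
    """Draw one synthetic dataset; bit-reproducible from ``scn.seed``."""
    rng = np.random.default_rng(scn.seed)
    percents = np.linspace(0.0, 100.0, scn.n_levels)
    days = [21 + 7 * t for t in range(scn.n_timepoints)]

    sample_ids, pct_list, day_list = [], [], []
    for pct in percents:
        for day in days:
            sample_ids.append(f"{scn.cosubstrate}{int(round(pct)):03d}_d{day}")
            pct_list.append(pct)
            day_list.append(day)
    n_samples = len(sample_ids)
    pct_arr = np.asarray(pct_list)
    g = pct_arr / 100.0 - 0.5
    m = 1.0 - ((pct_arr - 50.0) / 50.0) ** 2

    otu_ids = [f"otu_{j + 1}" for j in range(scn.n_otus)]
    groups = np.repeat(GROUPS, scn.group_sizes)
    groups = rng.permutation(groups)

    baseline = np.empty(scn.n_otus)
    beta = np.zeros(scn.n_otus)
    gamma = np.zeros(scn.n_otus)
    for j, grp in enumerate(groups):
        if grp == "inactive":
            baseline[j] = rng.normal(scn.inactive_baseline_mean, scn.inactive_baseline_sd)
        else:
            baseline[j] = rng.normal(scn.active_baseline_mean, scn.baseline_sd)
            if grp == "gradient_pos":
                beta[j] = scn.effect_size
            elif grp == "gradient_neg":
                beta[j] = -scn.effect_size
            else:
                gamma[j] = scn.effect_size * scn.mixture_effect_scale

    # samples x otus linear predictor -> compositional expectation; both
    # latents enter centered so neither shifts the overall community mass
    eta = baseline[None, :] + np.outer(g, beta) + np.outer(m - 0.5, gamma)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)

    sigma = np.sqrt(np.log1p(scn.depth_cv ** 2))
    depths = rng.lognormal(np.log(scn.depth) - sigma ** 2 / 2, sigma, size=n_samples)
    mu = depths[:, None] * p
    k = scn.dispersion
    counts = rng.negative_binomial(k, k / (k + mu))  # mean mu, var mu + mu^2/k

    counts_df = pd.DataFrame(counts.T, index=otu_ids, columns=sample_ids)
    otu_table = OtuTable(counts=counts_df)

    taxonomy = _generate_taxonomy(otu_ids, scn, rng)

    meta = pd.DataFrame(
        {
            "cosubstrate": [scn.cosubstrate if p_ > 0 else "none" for p_ in pct_list],
            "percent_cosubstrate": pct_list,
            "day": day_list,
            "dataset": scn.cosubstrate,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata = SampleMetadata(table=meta)

    latents = {"gradient": g, "mixture": m}
    marker_vals = {}
    units = {}
    for cpl in scn.marker_couplings:
        latent = latents[cpl.latent]
        marker_vals[cpl.name] = (
            cpl.intercept + cpl.slope * latent + rng.normal(0, cpl.noise_sd, n_samples)
        )
        units[cpl.name] = cpl.unit
    markers = PerformanceTable(
        values=pd.DataFrame(marker_vals, index=pd.Index(sample_ids, name="sample_id")),
        units=units,
    )

    truth = SyntheticTruth(
        otu_groups=pd.Series(groups, index=pd.Index(otu_ids, name="otu_id")),
        gradient=pd.Series(g, index=sample_ids),
        mixture=pd.Series(m, index=sample_ids),
        marker_couplings=list(scn.marker_couplings),
    )
    return SyntheticData(otu_table, taxonomy, metadata, markers, truth)


def _generate_taxonomy(otu_ids, scn: SyntheticScenario, rng) -> TaxonomyTable:
    n = len(otu_ids)
    is_archaea = rng.random(n) < scn.archaea_fraction
    rows = {}
    for otu, arch in zip(otu_ids, is_archaea):
        pool = ARCHAEA_LINEAGES if arch else BACTERIA_LINEAGES
        lineage = list(pool[rng.integers(len(pool))])
        if rng.random() < scn.unclassified_prob:
            cut = rng.integers(3, len(RANKS))  # keep at least domain/phylum/class
            lineage[cut:] = [UNKNOWN] * (len(RANKS) - cut)
        rows[otu] = lineage
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyTable(lineages=table)


# ---------------------------------------------------------------------------
# Parameter-recovery metrics
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    score_gradient_r: float
    selection_precision: float
    selection_recall: float
    f1: float


def recovery_metrics(
    truth: SyntheticTruth, model: CcaModel, selection: SelectionResult
) -> RecoveryMetrics:
    """How well CC1 recovers the planted gradient and its responsive OTUs.

    ``score_gradient_r`` is |Pearson r| between CC1 scores and the planted
    gradient; precision/recall compare the CC1 S-plot selection with the
    union of the two gradient-responding groups.  An empty selection has
    precision and recall 0 by convention.
    """
    g = truth.gradient.reindex(model.sample_ids).to_numpy()
    t = model.scores.iloc[:, 0].to_numpy()
    r = abs(stats.pearsonr(t, g)[0]) if t.std() > 0 else 0.0

    predicted = set(selection.otus(1))
    actual = set(truth.gradient_otus())
    tp = len(predicted & actual)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(actual) if actual else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return RecoveryMetrics(
        score_gradient_r=float(r),
        selection_precision=precision,
        selection_recall=recall,
        f1=f1,
    )
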