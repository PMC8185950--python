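"""Seeded generator of multi-timepoint Hi-C, expression and capture data.

The generator plants every structure the downstream analyses measure, at the
sampling design of the study it emulates: four Zeitgeber times (ZT0/6/12/18),
three Hi-C replicates and four RNA replicates per timepoint, plaid A/B
compartment structure with a subset of bins switching sign over the day
(oscillatory chromatin compartments), time-invariant TAD blocks, cosine
circadian expression with acrophases restricted to the sampled ZTs, hourly
phased enhancers, and promoter-interaction counts with distance decay and
planted stable vs phase-locked dynamic contacts.

Hi-C counts are Poisson (the eigenvector and insulation statistics they feed
need no extra dispersion); capture counts are negative binomial because they
feed a dispersion-aware differential test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genome import FeatureSet, GenomeDef, GenomicInterval, RestrictionMap, ZT_TIMEPOINTS
from .io import InteractionTable
from .matrix import ContactMatrix

__all__ = ["SimConfig", "ArchitectureTruth", "simulate_truth", "simulate_hic",
           "simulate_expression", "simulate_pchic", "simulate_activity_track"]


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults describe a toy genome (2 chromosomes x 20 Mb) small enough for
    desk-scale runs while preserving every planted structure.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 20_000_000
    bin_size_compartment: int = 100_000
    bin_size_tad: int = 50_000
    fragment_mean: int = 4_000
    timepoints: tuple[int, ...] = ZT_TIMEPOINTS
    hic_replicates: int = 3
    rna_replicates: int = 4
    hic_depth: float = 1000.0            # Poisson scale of the contact model
    occ_fraction: float = 0.2            # fraction of compartment bins that switch
    compartment_contrast: float = 1.0    # delta: same-compartment contact boost
    tad_enrichment: float = 3.0          # tau: within-TAD contact boost
    decay_exponent: float = 1.0          # alpha of the (1+d)^-alpha decay
    dispersion: float = 0.1              # phi of the NB capture counts
    n_genes: int = 300
    circadian_fraction: float = 0.3
    phase_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    amplitude: float = 1.0               # A of the cosine expression model
    expression_sigma: float = 0.2        # lognormal noise on FPKM
    baseline_fpkm: float = 20.0
    n_enhancers: int = 200
    fraction_dynamic_contacts: float = 0.3
    dynamic_fold: float = 4.0
    contact_mean: float = 30.0           # NB mean of planted capture contacts
    contacts_per_bait: int = 12          # typical promoter interactome size
    pp_contacts_per_circadian: int = 2   # extra promoter-promoter circadian edges
    n_background_contacts: int = 200
    background_mean: float = 3.0
    enhancer_wiring_frac: float = 0.4    # circadian other-ends placed at phased enhancers
    circadian_in_occ: float = 0.7        # circadian TSS placed inside OCC bins
    score_threshold: float = 5.0
    # emulate core-clock genes: fewer contacts, higher dynamic fraction
    core_clock_emulation: bool = True
    core_contact_scale: float = 0.6
    # overshoots the target observed fraction because stable promoter-promoter
    # and background records on the same bait dilute the realised value
    core_dynamic_scale: float = 2.0

    def __post_init__(self):
        if not (0 <= self.occ_fraction <= 1):
            raise ConfigError("occ_fraction outside [0, 1]")
        if not (0 <= self.circadian_fraction <= 1):
            raise ConfigError("circadian_fraction outside [0, 1]")
        for name in ("fraction_dynamic_contacts", "enhancer_wiring_frac",
                     "circadian_in_occ"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} outside [0, 1]")
        if abs(sum(self.phase_probs) - 1) > 1e-9:
            raise ConfigError("phase_probs must sum to 1")
        if self.compartment_contrast < 0 or self.amplitude < 0:
            raise ConfigError("contrast and amplitude must be >= 0")
        if self.tad_enrichment < 1:
            raise ConfigError("tad_enrichment must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ArchitectureTruth:
    """Planted ground truth: everything needed to score recovery."""

    config: SimConfig
    genome: GenomeDef
    fragmap: RestrictionMap
    # per chrom: (n_comp_bins, n_timepoints) array of "A"/"B"
    comp_labels: dict[str, np.ndarray]
    occ_bins: dict[str, np.ndarray]          # per chrom boolean
    tads: dict[str, list[tuple[int, int]]]   # per chrom TAD intervals in bp
    genes: pd.DataFrame      # gene_id, chrom, tss, bait_frag, circadian, phase, baseline
    enhancers: pd.DataFrame  # chrom, start, end, frag, phase_hr, oscillatory
    interactions: pd.DataFrame  # bait_frag, other_frag, klass, peak_zt, is_bait_bait
    planted_features: FeatureSet = field(default=None)  # at 50% of other-ends

    @property
    def timepoints(self) -> tuple[int, ...]:
        return self.config.timepoints

    def tad_boundaries(self, chrom: str) -> np.ndarray:
        """Interior boundary positions (bp) between consecutive TADs."""
        return np.array([s for s, _ in self.tads[chrom][1:]], dtype=np.int64)

    def occ_category(self, chrom: str, b: int) -> str:
        return "".join(self.comp_labels[chrom][b])

    @property
    def circadian_gene_ids(self) -> list[str]:
        return list(self.genes.loc[self.genes["circadian"], "gene_id"])

    @property
    def dynamic_interactions(self) -> pd.DataFrame:
        return self.interactions[self.interactions["klass"] == "dynamic"]

    @property
    def bait_universe(self) -> set[int]:
        return set(self.genes["bait_frag"])


def _derive_rng(seed: int, *keys) -> np.random.Generator:
    """Stable sub-stream derivation (process-independent, unlike ``hash``)."""
    import zlib

    tags = [zlib.crc32(repr(k).encode()) & 0x7FFFFFFF for k in keys]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


def simulate_truth(config: SimConfig) -> ArchitectureTruth:
    """Draw the planted architecture. Deterministic under a fixed seed."""
    rng = _derive_rng(config.seed, "truth")
    genome = GenomeDef.from_pairs(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chrom)
    )
    fragmap = RestrictionMap.from_random_sizes(genome, config.fragment_mean, rng)
    n_t = len(config.timepoints)

    comp_labels, occ_bins = {}, {}
    for chrom in genome.names:
        n_bins = genome.n_bins(chrom, config.bin_size_compartment)
        # plaid base: alternating A/B blocks of geometric mean ~5 bins
        base = np.empty(n_bins, dtype="<U1")
        label, i = ("A", "B")[rng.integers(2)], 0
        while i < n_bins:
            size = max(2, int(rng.geometric(1 / 5)))
            base[i:i + size] = label
            label = "B" if label == "A" else "A"
            i += size
        occ = rng.random(n_bins) < config.occ_fraction
        labels = np.tile(base[:, None], (1, n_t))
        flip = {"A": "B", "B": "A"}
        for b in np.flatnonzero(occ):
            k = rng.integers(1, n_t)  # flip at 1..n_t-1 timepoints: both letters kept
            which = rng.choice(n_t, size=k, replace=False)
            labels[b, which] = flip[base[b]]
        comp_labels[chrom] = labels
        occ_bins[chrom] = occ

    tads = {}
    for chrom in genome.names:
        length = genome.length(chrom)
        bounds, pos = [0], 0
        while pos < length:
            size = int(rng.integers(6, 17)) * config.bin_size_tad  # 300-800 kb
            pos = min(pos + size, length)
            bounds.append(pos)
        tads[chrom] = list(zip(bounds[:-1], bounds[1:]))

    genes = _place_genes(config, genome, fragmap, comp_labels, occ_bins, rng)
    enhancers = _place_enhancers(config, genome, fragmap, rng)
    interactions = _plant_interactions(config, genome, fragmap, genes, enhancers, rng)

    # features planted at half the unique other-ends (for enrichment scoring)
    non_bait = interactions.loc[~interactions["is_bait_bait"], "other_frag"].unique()
    chosen = rng.choice(non_bait, size=len(non_bait) // 2, replace=False)
    planted = FeatureSet(
        "planted_otherend_features",
        [fragmap.interval(int(f)) for f in sorted(chosen)],
    )

    return ArchitectureTruth(config, genome, fragmap, comp_labels, occ_bins,
                             tads, genes, enhancers, interactions, planted)


def _place_genes(config, genome, fragmap, comp_labels, occ_bins, rng) -> pd.DataFrame:
    n_t = len(config.timepoints)
    n_circ = int(round(config.n_genes * config.circadian_fraction))
    rows = []
    used_frags: set[int] = set()
    for g in range(config.n_genes):
        circadian = g < n_circ
        phase = (int(rng.choice(config.timepoints, p=config.phase_probs))
                 if circadian else int(rng.choice(config.timepoints)))
        chrom = genome.names[rng.integers(len(genome.names))]
        labels = comp_labels[chrom]
        t_idx = config.timepoints.index(phase)
        if circadian:
            # preferentially inside OCC bins that are A at the acrophase
            in_occ = rng.random() < config.circadian_in_occ
            pool = np.flatnonzero(
                (labels[:, t_idx] == "A") & (occ_bins[chrom] == in_occ)
            )
            if len(pool) == 0:
                pool = np.flatnonzero(labels[:, t_idx] == "A")
        else:
            pool = np.arange(labels.shape[0])
        b = int(rng.choice(pool))
        pos = int(b * config.bin_size_compartment
                  + rng.integers(config.bin_size_compartment))
        pos = min(pos, genome.length(chrom) - 1)
        frag = fragmap.fragment_at(chrom, pos)
        if frag in used_frags:  # one promoter per fragment
            frag = next((f for f in fragmap.fragments_on(chrom)
                         if f not in used_frags), frag)
        used_frags.add(frag)
        tss = fragmap.interval(frag).start  # genes sit at fragment boundaries
        rows.append({
            "gene_id": f"gene{g:04d}", "chrom": chrom, "tss": tss,
            "bait_frag": frag, "circadian": circadian,
            "phase": phase if circadian else -1,
            "baseline": float(config.baseline_fpkm * rng.lognormal(0, 0.3)),
        })
    df = pd.DataFrame(rows)
    df["is_core"] = False
    if config.core_clock_emulation:
        from .interactome import CORE_CLOCK_GENES

        circ_idx = df.index[df["circadian"]][:len(CORE_CLOCK_GENES)]
        for i, name in zip(circ_idx, CORE_CLOCK_GENES):
            df.loc[i, "gene_id"] = name
            df.loc[i, "is_core"] = True
    return df


def _place_enhancers(config, genome, fragmap, rng) -> pd.DataFrame:
    rows = []
    # oscillatory eRNAs are the minority of liver enhancers; keeping the
    # non-oscillatory pool strictly larger also keeps equal-size resampling
    # nulls non-degenerate
    n_osc = int(config.n_enhancers * 0.4)
    used: set[int] = set()
    for e in range(config.n_enhancers):
        for _ in range(50):  # redraw on fragment collision
            chrom = genome.names[rng.integers(len(genome.names))]
            pos = int(rng.integers(genome.length(chrom) - 2000))
            frag = fragmap.fragment_at(chrom, pos)
            if frag not in used:
                break
        used.add(frag)
        iv = fragmap.interval(frag)
        oscillatory = e < n_osc
        rows.append({
            "chrom": chrom, "start": iv.start, "end": iv.end, "frag": frag,
            "phase_hr": float(rng.integers(24)) if oscillatory else np.nan,
            "oscillatory": oscillatory,
        })
    return pd.DataFrame(rows).reset_index(drop=True)


def _plant_interactions(config, genome, fragmap, genes, enhancers, rng) -> pd.DataFrame:
    rows = []
    bait_set = set(genes["bait_frag"])
    osc_enh = enhancers[enhancers["oscillatory"]]
    seen: set[tuple[int, int]] = set()

    def add(bait, other, klass, peak):
        key = (min(bait, other), max(bait, other))
        if bait == other or key in seen:
            return
        seen.add(key)
        rows.append({"bait_frag": int(bait), "other_frag": int(other),
                     "klass": klass, "peak_zt": peak,
                     "is_bait_bait": other in bait_set})

    for _, g in genes.iterrows():
        bait = int(g["bait_frag"])
        chrom = g["chrom"]
        mid = fragmap.midpoint(bait)
        is_core = bool(g.get("is_core", False))
        n_contacts = (max(2, round(config.contacts_per_bait * config.core_contact_scale))
                      if is_core else config.contacts_per_bait)
        p_dyn = (min(1.0, config.fraction_dynamic_contacts * config.core_dynamic_scale)
                 if is_core else config.fraction_dynamic_contacts)
        for _ in range(n_contacts):
            dynamic = bool(g["circadian"]) and rng.random() < p_dyn
            peak = int(g["phase"]) if dynamic else int(rng.choice(config.timepoints))
            # phase-locked wiring to oscillatory enhancers near the acrophase
            if (bool(g["circadian"]) and len(osc_enh)
                    and rng.random() < config.enhancer_wiring_frac):
                target_phase = g["phase"]
                diff = np.minimum(np.abs(osc_enh["phase_hr"] - target_phase),
                                  24 - np.abs(osc_enh["phase_hr"] - target_phase))
                near = osc_enh[diff <= 3]
                # promoter-enhancer contacts are short-range: stay within 2 Mb
                if len(near):
                    enh_mid = (near["start"] + near["end"]) // 2
                    near = near[(near["chrom"] == chrom)
                                & (np.abs(enh_mid - mid) <= 2_000_000)]
                if len(near):
                    other = int(near.iloc[rng.integers(len(near))]["frag"])
                    add(bait, other, "dynamic" if dynamic else "stable", peak)
                    continue
            # distance-decay other end: log-uniform 20 kb .. 1 Mb, random side
            d = int(10 ** rng.uniform(np.log10(2e4), 6))
            pos = mid + d * (1 if rng.random() < 0.5 else -1)
            pos = int(np.clip(pos, 0, genome.length(chrom) - 1))
            other = fragmap.fragment_at(chrom, pos)
            add(bait, other, "dynamic" if dynamic else "stable", peak)

    # extra assortative circadian promoter-promoter edges (same diel class)
    circ = genes[genes["circadian"]]
    diurnal = circ[circ["phase"].isin([0, 6])]
    nocturnal = circ[circ["phase"].isin([12, 18])]
    for group in (diurnal, nocturnal):
        idx = group.index.to_numpy()
        for i in idx:
            for _ in range(config.pp_contacts_per_circadian):
                j = int(rng.choice(idx))
                if j == i:
                    continue
                add(int(genes.loc[i, "bait_frag"]), int(genes.loc[j, "bait_frag"]),
                    "stable", int(genes.loc[i, "phase"]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hi-C counts

def _comp_factor(labels_t: np.ndarray, delta: float) -> np.ndarray:
    same = labels_t[:, None] == labels_t[None, :]
    return 1.0 + delta * same


def simulate_hic(truth: ArchitectureTruth, timepoint: int, replicate: int,
                 depth: float | None = None, seed: int | None = None,
                 chrom: str | None = None,
                 bin_size: int | None = None) -> ContactMatrix:
    """Poisson contact counts under the plaid + domain + decay model.

    mean[i, j] = depth * (1+d)^-alpha * (1 + delta*[same compartment at t])
    * (tau if same TAD else 1); the upper triangle is drawn and mirrored.
    """
    cfg = truth.config
    if depth is None:
        depth = cfg.hic_depth
    if depth < 0:
        raise ValueError("depth must be >= 0")
    chrom = chrom or truth.genome.names[0]
    bin_size = bin_size or cfg.bin_size_compartment
    if timepoint not in cfg.timepoints:
        raise ValueError(f"timepoint {timepoint} not simulated")
    t_idx = cfg.timepoints.index(timepoint)

    n_bins = truth.genome.n_bins(chrom, bin_size)
    # compartment labels defined on the compartment grid; map to this grid
    ratio = cfg.bin_size_compartment // bin_size
    comp = truth.comp_labels[chrom][:, t_idx]
    if ratio > 1:
        comp = np.repeat(comp, ratio)[:n_bins]
    elif ratio == 0:  # coarser than the compartment grid
        step = bin_size // cfg.bin_size_compartment
        comp = comp[::step][:n_bins]

    tad_id = np.full(n_bins, -1)
    for k, (s, e) in enumerate(truth.tads[chrom]):
        tad_id[s // bin_size: -(-e // bin_size)] = k

    i = np.arange(n_bins)
    d = np.abs(i[:, None] - i[None, :])
    mu = (1.0 + d) ** (-cfg.decay_exponent)
    mu = mu * _comp_factor(comp, cfg.compartment_contrast)
    same_tad = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    mu = mu * np.where(same_tad, cfg.tad_enrichment, 1.0)

    rng = _derive_rng(seed if seed is not None else cfg.seed,
                      "hic", chrom, timepoint, replicate, bin_size)
    counts = rng.poisson(depth * mu)
    counts = np.triu(counts) + np.triu(counts, 1).T  # symmetric draw
    return ContactMatrix(chrom, bin_size, counts.astype(float),
                         timepoint=timepoint, replicate=f"R{replicate}")


def simulate_activity_track(truth: ArchitectureTruth, chrom: str,
                            bin_size: int | None = None):
    """Planted gene-density covariate for orienting compartment eigenvectors.

    A-compartment bins (majority label over timepoints) get high signal; the
    analogue of an active-chromatin coverage track.
    """
    from .genome import CoverageTrack

    cfg = truth.config
    bin_size = bin_size or cfg.bin_size_compartment
    labels = truth.comp_labels[chrom]
    a_frac = (labels == "A").mean(axis=1)
    n_bins = truth.genome.n_bins(chrom, bin_size)
    ratio = cfg.bin_size_compartment // bin_size
    vals = np.repeat(a_frac, ratio)[:n_bins] if ratio > 1 else a_frac[:n_bins]
    gene_density = np.zeros(n_bins)
    sub = truth.genes[truth.genes["chrom"] == chrom]
    for tss in sub["tss"]:
        b = tss // bin_size
        if b < n_bins:
            gene_density[b] += 1
    return CoverageTrack(chrom, bin_size, vals + 0.1 * gene_density, "raw")


# ---------------------------------------------------------------------------
# Expression

def simulate_expression(truth: ArchitectureTruth, config: SimConfig | None = None,
                        seed: int | None = None) -> ExpressionMatrix:
    """Cosine circadian means with multiplicative lognormal noise.

    Circadian gene mean at time t: baseline * (1 + A*cos(2*pi*(t-phase)/24));
    flat genes sit at baseline. Noise is mean-preserving lognormal.
    """
    cfg = config or truth.config
    rng = _derive_rng(seed if seed is not None else cfg.seed, "expression")
    genes = truth.genes
    sigma = cfg.expression_sigma
    cols = {
        "gene_id": genes["gene_id"].to_numpy(),
        "tss_chrom": genes["chrom"].to_numpy(),
        "tss_pos": genes["tss"].to_numpy(),
        "strand": np.full(len(genes), "+"),
    }
    for t in cfg.timepoints:
        osc = 1.0 + cfg.amplitude * np.cos(2 * np.pi * (t - genes["phase"]) / 24.0)
        mean_t = np.where(genes["circadian"], genes["baseline"] * osc,
                          genes["baseline"])
        for r in range(1, cfg.rna_replicates + 1):
            noise = rng.lognormal(-sigma**2 / 2, sigma, size=len(genes))
            cols[f"fpkm_ZT{t}_R{r}"] = np.maximum(mean_t * noise, 0.0)
    return ExpressionMatrix(pd.DataFrame(cols))


# ---------------------------------------------------------------------------
# Capture Hi-C

def _nb_draw(rng, mean, phi, size=None):
    """Negative binomial via gamma-Poisson; Poisson in the phi -> 0 limit."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(1.0 / phi, phi * mean, size=size)
    return rng.poisson(lam)


def simulate_pchic(truth: ArchitectureTruth, config: SimConfig | None = None,
                   seed: int | None = None) -> InteractionTable:
    """Capture interaction table with NB counts and per-timepoint scores.

    Stable contacts keep a constant mean; dynamic contacts are boosted
    ``dynamic_fold``-fold at their peak timepoint. Planted records score above
    the significance threshold at their active timepoints; background pairs
    score below it.
    """
    cfg = config or truth.config
    rng = _derive_rng(seed if seed is not None else cfg.seed, "pchic")
    planted = truth.interactions
    fragmap = truth.fragmap
    thr = cfg.score_threshold

    rows = []
    for _, it in planted.iterrows():
        row = {"bait_frag": it["bait_frag"], "other_frag": it["other_frag"]}
        for t in cfg.timepoints:
            peak = (it["klass"] == "dynamic" and t == it["peak_zt"])
            mean = cfg.contact_mean * (cfg.dynamic_fold if peak else 1.0)
            counts = _nb_draw(rng, mean, cfg.dispersion, size=cfg.hic_replicates)
            for r, c in enumerate(counts, 1):
                row[f"count_ZT{t}_R{r}"] = int(c)
            active = it["klass"] == "stable" or t == it["peak_zt"]
            row[f"score_ZT{t}"] = float(thr + 1 + rng.random() * 2) if active \
                else float(rng.random() * (thr - 1))
        rows.append(row)

    # distance-decay background pairs, low counts, sub-threshold scores
    baits = truth.genes["bait_frag"].to_numpy()
    for _ in range(cfg.n_background_contacts):
        bait = int(rng.choice(baits))
        chrom = fragmap.chrom_of(bait)
        d = int(10 ** rng.uniform(np.log10(2e4), 6))
        pos = int(np.clip(fragmap.midpoint(bait)
                          + d * (1 if rng.random() < 0.5 else -1),
                          0, truth.genome.length(chrom) - 1))
        other = fragmap.fragment_at(chrom, pos)
        if other == bait:
            continue
        row = {"bait_frag": bait, "other_frag": other}
        for t in cfg.timepoints:
            counts = _nb_draw(rng, cfg.background_mean, cfg.dispersion,
                              size=cfg.hic_replicates)
            for r, c in enumerate(counts, 1):
                row[f"count_ZT{t}_R{r}"] = int(c)
            row[f"score_ZT{t}"] = float(rng.random() * (thr - 1))
        rows.append(row)

    df = pd.DataFrame(rows)
    df["score"] = df[[f"score_ZT{t}" for t in cfg.timepoints]].max(axis=1)
    df["distance_bp"] = [
        np.nan if (d := fragmap.distance(int(b), int(o))) is None else float(d)
        for b, o in zip(df["bait_frag"], df["other_frag"])
    ]
    baits_set = set(truth.genes["bait_frag"])
    df["is_bait_bait"] = df["other_frag"].isin(baits_set)
    # drop duplicate pairs introduced by background draws
    key = df.apply(lambda r: (min(r["bait_frag"], r["other_frag"]),
                              max(r["bait_frag"], r["other_frag"])), axis=1)
    df = df.loc[~key.duplicated()].reset_index(drop=True)
    return InteractionTable(df, fragmap, baits_set)
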