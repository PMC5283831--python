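"""Synthetic-data generators for every pipeline input.

These generators produce the downstream products the analysis consumes —
TSS/expression tables, differential-expression (DE) tables, peak intervals,
peak sequences and plate-reader tables — with *planted* effect sizes, so
every stage can be tested end-to-end with known truth and no external data.

Distributional choices (all package decisions; the analyses make no use of
them): TSS positions uniform per chromosome; expression log-normal (log10
mean/sd); background peaks uniform; planted peak offsets exponential with a
random sign; plate noise multiplicative Gaussian with a fixed coefficient of
variation.  Every generator is a pure function of (config, seed).

Two generators carry calibration oracles:

* :func:`gen_peaks` tunes the exponential offset scale of the peaks planted
  near down-regulated TSSs by bisection against a brute-force simulation of
  the generator itself, so that the *expected* ratio (median nearest-peak
  distance of background-only genes) / (same for down genes) hits the
  requested ``planted_fold``.  There is no convenient closed form for the
  median of min(planted offset, nearest background peak), hence the
  simulation oracle.
* :func:`gen_motif_peaks` tunes the fraction of sequences receiving a motif
  insertion so the expected total fraction with >= 1 hit (background hits
  included) equals the target, using an analytic background estimate refined
  by a Monte-Carlo scan of 10,000 background sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif import Motif, IUPAC, reverse_complement, peak_hit_fraction
from .proximity import nearest_peak_distance
from .alphascreen import TitrationSeries, DoseResponseData

__all__ = [
    "GenomeConfig",
    "ProximityScenario",
    "AlphaScenario",
    "AlphaPanelScenario",
    "MotifScenario",
    "gen_genome",
    "gen_de_table",
    "gen_peaks",
    "gen_dose_response",
    "gen_titration",
    "gen_alpha_panel",
    "gen_motif_peaks",
    "SCENARIOS",
    "build_scenario",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    """A toy genome: chromosome sizes, gene count and an expression law.

    ``expression_law`` is ``(mean, sd)`` of log10 expression; expression is
    drawn as ``10**Normal(mean, sd)`` (log-normal, arbitrary TPM-like units).
    """

    chrom_sizes: dict[str, int]
    n_genes: int
    expression_law: tuple[float, float] = (1.5, 0.75)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_sizes or any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("all chromosome lengths must be positive")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_genes > sum(self.chrom_sizes.values()):
            raise ValueError("more genes requested than placeable positions")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class ProximityScenario:
    """Planted peak-proximity enrichment.

    ``planted_fold`` is the target ratio f*: down-regulated genes end up
    f*-times closer to the nearest peak than background-only genes.
    """

    genome: GenomeConfig
    n_down: int
    n_up: int
    n_unchanged: int
    n_background_peaks: int
    planted_fold: float
    peak_len: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_fold < 1:
            raise ValueError("planted_fold must be >= 1")
        if self.n_down + self.n_up + self.n_unchanged != self.genome.n_genes:
            raise ValueError("group counts must sum to n_genes")
        if self.peak_len <= 0 or self.peak_len >= min(self.genome.chrom_sizes.values()):
            raise ValueError("peak_len must be positive and fit in every chromosome")


@dataclass(frozen=True)
class AlphaScenario:
    """Planted dose-response: a three-parameter inhibition curve plus noise."""

    true_ic50: float  # µM
    top: float = 100.0
    bottom: float = 0.0
    concentrations: tuple[float, ...] = (0.3, 0.94868, 3.0, 9.4868, 30.0, 94.868, 300.0)
    n_replicates: int = 3
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.top > self.bottom >= 0:
            raise ValueError("need top > bottom >= 0")
        c = np.asarray(self.concentrations)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.true_ic50 <= 0:
            raise ValueError("true_ic50 must be positive")


@dataclass(frozen=True)
class AlphaPanelScenario:
    """A panel of interacting pairs, a subset with planted compound disruption."""

    n_pairs: int = 12
    disrupted_pct: tuple[float, ...] = (40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
    undisrupted_pct: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    noise_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.disrupted_pct) + len(self.undisrupted_pct) != self.n_pairs:
            raise ValueError("planted disruption values must cover all pairs")


@dataclass(frozen=True)
class MotifScenario:
    """Peak sequences with a calibrated fraction carrying a consensus motif."""

    n_peaks: int
    peak_seq_len: int
    motif: str = "TGASTCA"
    gc_content: float = 0.5
    target_hit_fraction: float = 0.0323
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_hit_fraction <= 1:
            raise ValueError("target_hit_fraction must be in [0, 1]")
        if self.peak_seq_len < len(self.motif):
            raise ValueError("peak_seq_len must be >= motif length")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")


# ---------------------------------------------------------------------------
# genome / DE / peaks
# ---------------------------------------------------------------------------


def gen_genome(config: GenomeConfig) -> pd.DataFrame:
    """Generate a TSS table: one row per gene.

    Columns ``gene_id, chrom, tss, strand, expression``.  Genes are spread
    over chromosomes proportionally to length, TSS positions uniform,
    strands random, expression log-normal per ``expression_law``.
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    counts = rng.multinomial(config.n_genes, sizes / sizes.sum())
    rows = []
    g = 0
    for chrom, n in zip(chroms, counts):
        length = config.chrom_sizes[chrom]
        pos = rng.integers(0, length, size=n)
        for p in np.sort(pos):
            rows.append((f"gene{g:05d}", chrom, int(p)))
            g += 1
    tss = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])
    tss["strand"] = rng.choice(["+", "-"], size=len(tss))
    mu, sd = config.expression_law
    tss["expression"] = 10.0 ** rng.normal(mu, sd, size=len(tss))
    return tss


def gen_de_table(tss: pd.DataFrame, scenario: ProximityScenario) -> pd.DataFrame:
    """Generate a DE table with planted down / up / unchanged groups.

    Down genes get ``log2fc < -1`` and ``padj < 0.05``; up symmetric;
    unchanged genes get ``|log2fc| < 1`` (any padj).  The planted group is
    recorded in a ``group_true`` column for round-trip tests.
    """
    if scenario.n_down + scenario.n_up > len(tss):
        raise ValueError("scenario group counts exceed the number of genes")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    genes = tss["gene_id"].to_numpy()
    perm = rng.permutation(len(genes))
    down = perm[: scenario.n_down]
    up = perm[scenario.n_down: scenario.n_down + scenario.n_up]
    lfc = np.clip(rng.normal(0, 0.4, size=len(genes)), -0.99, 0.99)
    padj = rng.uniform(0.001, 1.0, size=len(genes))
    lfc[down] = -(1.2 + rng.exponential(0.8, size=len(down)))
    lfc[up] = 1.2 + rng.exponential(0.8, size=len(up))
    padj[down] = 10.0 ** rng.uniform(-6, np.log10(0.049), size=len(down))
    padj[up] = 10.0 ** rng.uniform(-6, np.log10(0.049), size=len(up))
    group = np.full(len(genes), "unchanged", dtype=object)
    group[down] = "down"
    group[up] = "up"
    return pd.DataFrame({
        "gene_id": genes, "log2fc": lfc, "padj": padj, "group_true": group,
    })


def _place_peaks(tss: pd.DataFrame, down_genes: np.ndarray,
                 scenario: ProximityScenario, scale: float | None,
                 rng: np.random.Generator) -> pd.DataFrame:
    """One realisation of the peak generator at a given planted offset scale."""
    cfg = scenario.genome
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    counts = rng.multinomial(scenario.n_background_peaks, sizes / sizes.sum())
    half = scenario.peak_len // 2
    recs = []
    for chrom, n in zip(chroms, counts):
        length = cfg.chrom_sizes[chrom]
        mids = rng.integers(half, length - (scenario.peak_len - half), size=n)
        for m in mids:
            recs.append((chrom, int(m) - half))
    if scale is not None:
        sub = tss[tss["gene_id"].isin(down_genes)]
        offs = rng.exponential(scale, size=len(sub))
        signs = rng.choice([-1, 1], size=len(sub))
        for (_, row), off, sgn in zip(sub.iterrows(), offs, signs):
            length = cfg.chrom_sizes[row["chrom"]]
            mid = int(round(row["tss"] + sgn * off))
            mid = min(max(mid, half), length - (scenario.peak_len - half) - 1)
            recs.append((row["chrom"], mid - half))
    peaks = pd.DataFrame(recs, columns=["chrom", "start"])
    peaks["end"] = peaks["start"] + scenario.peak_len
    peaks["summit_offset"] = half
    return peaks.sort_values(["chrom", "start"]).reset_index(drop=True)


def _achieved_ratio(tss: pd.DataFrame, down_genes: np.ndarray,
                    scenario: ProximityScenario, scale: float | None,
                    rng: np.random.Generator, n_reps: int) -> float:
    """Brute-force oracle: mean over replicates of
    median(background-gene distance) / median(down-gene distance)."""
    is_down = tss["gene_id"].isin(down_genes).to_numpy()
    ratios = np.empty(n_reps)
    for r in range(n_reps):
        peaks = _place_peaks(tss, down_genes, scenario, scale, rng)
        d = nearest_peak_distance(tss, peaks)["distance"].to_numpy()
        ratios[r] = np.median(d[~is_down]) / max(np.median(d[is_down]), 0.5)
    return float(ratios.mean())


def gen_peaks(tss: pd.DataFrame, de: pd.DataFrame,
              scenario: ProximityScenario,
              n_oracle_reps: int = 60) -> tuple[pd.DataFrame, dict]:
    """Generate a peak set with a planted proximity enrichment.

    Background peaks are uniform over the genome; each down-regulated gene
    additionally gets one peak whose summit sits at a signed exponential
    offset from its TSS.  The exponential scale is calibrated by bisection
    against a >= 50-replicate simulation of this same generator until the
    expected median-distance ratio is within 2% of ``planted_fold``
    (``planted_fold == 1`` plants nothing: the exact null).

    Returns ``(peaks, metadata)``; metadata records the calibrated scale and
    the oracle's achieved ratio.

    Raises
    ------
    ValueError
        If the fold is unattainable (would require sub-bp offsets).
    """
    ss = np.random.SeedSequence([scenario.seed, 2])
    rng_cal, rng_out = [np.random.default_rng(s) for s in ss.spawn(2)]
    down = de.loc[de["group_true"] == "down", "gene_id"].to_numpy() \
        if "group_true" in de.columns else \
        de.loc[(de["log2fc"] < -1) & (de["padj"] < 0.05), "gene_id"].to_numpy()

    meta: dict = {"planted_fold": scenario.planted_fold, "seed": scenario.seed,
                  "n_oracle_reps": n_oracle_reps}
    if scenario.planted_fold == 1.0 or len(down) == 0:
        scale = None
        meta.update(calibrated_scale=None, achieved_ratio_oracle=1.0)
    else:
        scale, achieved = _calibrate_scale(tss, down, scenario, rng_cal,
                                           n_oracle_reps)
        meta.update(calibrated_scale=scale, achieved_ratio_oracle=achieved)
    peaks = _place_peaks(tss, down, scenario, scale, rng_out)
    return peaks, meta


def _calibrate_scale(tss, down, scenario, rng, n_reps,
                     rel_tol: float = 0.02, max_iter: int = 40):
    fold = scenario.planted_fold
    lo = 1.0
    r_lo = _achieved_ratio(tss, down, scenario, lo, rng, n_reps)
    if r_lo < fold * (1 - rel_tol):
        raise ValueError(
            f"planted_fold {fold} unattainable: even 1-bp offsets only reach "
            f"a ratio of {r_lo:.2f}"
        )
    # expand hi until the ratio falls below the target
    hi = 1000.0
    r_hi = _achieved_ratio(tss, down, scenario, hi, rng, n_reps)
    while r_hi > fold and hi < scenario.genome.total_length:
        hi *= 4
        r_hi = _achieved_ratio(tss, down, scenario, hi, rng, n_reps)
    best_scale, best_err = lo, abs(r_lo - fold) / fold
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # bisect in log space: ratio ~ power of scale
        r_mid = _achieved_ratio(tss, down, scenario, mid, rng, n_reps)
        err = abs(r_mid - fold) / fold
        if err < best_err:
            best_scale, best_err = mid, err
        if err < rel_tol:
            return mid, r_mid
        if r_mid > fold:
            lo = mid
        else:
            hi = mid
    return best_scale, _achieved_ratio(tss, down, scenario, best_scale, rng,
                                       max(n_reps, 100))


# ---------------------------------------------------------------------------
# plate-reader generators
# ---------------------------------------------------------------------------


def gen_dose_response(scenario: AlphaScenario) -> DoseResponseData:
    """Percent-interaction vs concentration from the three-parameter model.

    Mean response at concentration x is
    ``bottom + (top - bottom) / (1 + x / true_ic50)`` (unit Hill slope);
    replicates receive multiplicative Gaussian noise with CV ``noise_cv``.
    """
    rng = np.random.default_rng(scenario.seed)
    x = np.asarray(scenario.concentrations, dtype=float)
    mean = scenario.bottom + (scenario.top - scenario.bottom) / (1 + x / scenario.true_ic50)
    noise = rng.normal(1.0, scenario.noise_cv,
                       size=(len(x), scenario.n_replicates)) if scenario.noise_cv > 0 \
        else np.ones((len(x), scenario.n_replicates))
    return DoseResponseData(concentrations=x, responses=mean[:, None] * noise)


def gen_titration(
    pair_strength: float,
    seed: int = 0,
    n_steps: int = 12,
    top_conc: float = 32.0,
    dilution_factor: float = 2.0,
    hook_conc: float = 1.0,
    amplitude: float = 2000.0,
    background: float = 100.0,
    noise_cv: float = 0.0,
    n_replicates: int = 3,
    pair_id: str | None = None,
) -> TitrationSeries:
    """A serial-dilution titration with the bead-saturation hook effect.

    Signal at lysate concentration c follows the unimodal hook curve::

        S(c) = A * c / (1 + (c / hook_conc)^2) + background

    with amplitude ``A = pair_strength * amplitude``: a positive interaction
    gives a bell-shaped series peaking at ``c = hook_conc``; pair_strength 0
    gives a flat background series (non-interactor).  Concentrations run
    ``top_conc / dilution_factor**step``.
    """
    if pair_strength < 0:
        raise ValueError("pair_strength must be non-negative")
    rng = np.random.default_rng(seed)
    conc = top_conc / dilution_factor ** np.arange(n_steps)
    a = pair_strength * amplitude
    mean = a * conc / (1.0 + (conc / hook_conc) ** 2) + background
    if noise_cv > 0:
        sig = mean[:, None] * rng.normal(1.0, noise_cv, size=(n_steps, n_replicates))
        sig = np.clip(sig, 0.0, None)
    else:
        sig = np.repeat(mean[:, None], n_replicates, axis=1)
    return TitrationSeries(dilution_steps=conc, signals=sig, pair_id=pair_id)


def gen_alpha_panel(scenario: AlphaPanelScenario) -> pd.DataFrame:
    """Vehicle/compound signals for a panel of interacting pairs.

    Each pair has a vehicle-condition signal (arbitrary luminescence) and a
    compound-condition signal reduced by the planted disruption percentage;
    replicates carry multiplicative noise.  Long format:
    ``pair_id, condition, replicate, signal, planted_disruption_pct``
    (the last column is generator truth for tests).
    """
    rng = np.random.default_rng(scenario.seed)
    planted = list(scenario.disrupted_pct) + list(scenario.undisrupted_pct)
    order = rng.permutation(scenario.n_pairs)
    rows = []
    for k, idx in enumerate(order):
        d = planted[idx]
        pair = f"pair{k:02d}"
        vehicle = rng.uniform(600.0, 1400.0)
        compound = vehicle * (1 - d / 100.0)
        for cond, mu in (("vehicle", vehicle), ("compound", compound)):
            for rep in range(scenario.n_replicates):
                sig = max(mu * rng.normal(1.0, scenario.noise_cv), 0.0)
                rows.append((pair, cond, rep, sig, d))
    return pd.DataFrame(rows, columns=["pair_id", "condition", "replicate",
                                       "signal", "planted_disruption_pct"])


# ---------------------------------------------------------------------------
# motif peaks
# ---------------------------------------------------------------------------


def analytic_background_hit_rate(motif: Motif | str, seq_len: int,
                                 gc: float = 0.5) -> float:
    """Analytic estimate of P(>= 1 consensus hit) for an i.i.d. sequence.

    Per-window probability is approximated as the sum of forward and
    reverse-complement match probabilities (union bound; an overestimate for
    self-reverse-complementary consensi), windows treated as independent.
    """
    if isinstance(motif, str):
        motif = Motif(motif)
    n_win = seq_len - len(motif) + 1
    if n_win <= 0:
        return 0.0
    p_f = motif.match_probability(gc)
    p_r = Motif(reverse_complement(motif.consensus)).match_probability(gc)
    p_win = min(p_f + p_r, 1.0)
    return 1.0 - (1.0 - p_win) ** n_win


def _random_sequences(n: int, length: int, gc: float,
                      rng: np.random.Generator) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=(n, length), p=p)
    return [bytes(row).decode("ascii") for row in codes]


def _expand_consensus(motif: Motif, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))]
                   for c in motif.consensus)


def gen_motif_peaks(scenario: MotifScenario, insert: bool = True,
                    n_mc: int = 10_000) -> tuple[pd.DataFrame, list[tuple[str, str]], dict]:
    """Peak sequences with a calibrated planted motif hit fraction.

    Background sequences are i.i.d. at the scenario GC content.  A Bernoulli
    fraction of them receive one concrete expansion of the IUPAC consensus
    (uniform over the degenerate set, random strand, random offset).  The
    insertion probability p is calibrated so the expected total fraction of
    sequences with >= 1 hit equals ``target_hit_fraction``::

        p = (target - b) / (1 - b)

    where b, the background hit rate, is estimated analytically and then
    refined by scanning ``n_mc`` Monte-Carlo background sequences.

    Returns ``(peaks, sequences, metadata)``: a toy peak table (one synthetic
    contig, concatenated intervals), ``(name, sequence)`` pairs, and the
    calibration metadata.

    Raises
    ------
    ValueError
        If the target is below the background hit rate (impossible to reach
        by inserting motifs); the message reports the computed rates.
    """
    motif = Motif(scenario.motif)
    ss = np.random.SeedSequence([scenario.seed, 3])
    rng_mc, rng_out = [np.random.default_rng(s) for s in ss.spawn(2)]

    b_analytic = analytic_background_hit_rate(motif, scenario.peak_seq_len,
                                              scenario.gc_content)
    mc = _random_sequences(n_mc, scenario.peak_seq_len, scenario.gc_content, rng_mc)
    _, _, b_mc = peak_hit_fraction(mc, motif)

    meta = {"analytic_background_rate": b_analytic,
            "mc_background_rate": b_mc, "n_mc": n_mc,
            "target_hit_fraction": scenario.target_hit_fraction,
            "seed": scenario.seed}
    if insert:
        if scenario.target_hit_fraction < b_mc:
            raise ValueError(
                f"target hit fraction {scenario.target_hit_fraction:.2%} is below "
                f"the background hit rate for {scenario.peak_seq_len}-bp sequences "
                f"(analytic ≈ {b_analytic:.2%}, Monte-Carlo ≈ {b_mc:.2%}); "
                "it cannot be reached by inserting motifs"
            )
        p_insert = (scenario.target_hit_fraction - b_mc) / (1.0 - b_mc)
    else:
        p_insert = 0.0
    meta["insert_fraction"] = p_insert

    seqs = _random_sequences(scenario.n_peaks, scenario.peak_seq_len,
                             scenario.gc_content, rng_out)
    # plant exactly round(p * n) motifs: same expectation as Bernoulli
    # insertion, without the binomial noise on the planted count
    n_insert = int(round(p_insert * scenario.n_peaks))
    inserted = np.zeros(scenario.n_peaks, dtype=bool)
    inserted[rng_out.choice(scenario.n_peaks, size=n_insert, replace=False)] = True
    m = len(motif)
    out = []
    for i, s in enumerate(seqs):
        if inserted[i]:
            site = _expand_consensus(motif, rng_out)
            if rng_out.random() < 0.5:
                site = reverse_complement(site)
            off = int(rng_out.integers(0, scenario.peak_seq_len - m + 1))
            s = s[:off] + site + s[off + m:]
        out.append((f"peak{i:05d}", s))
    meta["n_inserted"] = int(inserted.sum())

    gap = 100
    starts = np.arange(scenario.n_peaks) * (scenario.peak_seq_len + gap)
    peaks = pd.DataFrame({
        "chrom": "chrS", "start": starts,
        "end": starts + scenario.peak_seq_len,
        "summit_offset": scenario.peak_seq_len // 2,
    })
    return peaks, out, meta


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------


def _prox_genome(seed: int) -> GenomeConfig:
    return GenomeConfig(chrom_sizes={"chr1": 100_000_000}, n_genes=2000,
                        expression_law=(1.5, 0.75), seed=seed)


def build_scenario(name: str, seed: int = 0):
    """Instantiate a registered scenario with the given seed."""
    try:
        return SCENARIOS[name](seed)
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}") from None


#: Scenario registry: name -> factory(seed).  Planted values are the study
#: conditions each scenario emulates (IC50s of 3.3 and 65.9 µM, proximity
#: folds of 3.6 and 2.05, a 12-pair panel with 6 disrupted, a 3.23% motif
#: hit fraction).
SCENARIOS: dict = {
    "PROX-A": lambda seed=0: ProximityScenario(
        genome=_prox_genome(seed), n_down=300, n_up=300, n_unchanged=1400,
        n_background_peaks=3000, planted_fold=3.6, peak_len=200, seed=seed),
    "PROX-B": lambda seed=0: ProximityScenario(
        genome=_prox_genome(seed), n_down=300, n_up=300, n_unchanged=1400,
        n_background_peaks=3000, planted_fold=2.05, peak_len=200, seed=seed),
    "ALPHA-IC50-A": lambda seed=0: AlphaScenario(true_ic50=3.3, seed=seed),
    "ALPHA-IC50-B": lambda seed=0: AlphaScenario(true_ic50=65.9, seed=seed),
    "ALPHA-PANEL": lambda seed=0: AlphaPanelScenario(seed=seed),
    "MOTIF-A": lambda seed=0: MotifScenario(
        n_peaks=10_000, peak_seq_len=60, motif="TGASTCA", gc_content=0.5,
        target_hit_fraction=0.0323, seed=seed),
}
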