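"""Synthetic cohorts, experiments and CLIP data with known ground truth.

The generators emulate the statistical structure the downstream analyses
assume, so that every estimator in the package can be exercised against a
known answer:

* ``generate_cohort`` — a tumour cohort in which a splicing regulator's
  expression drives cassette-exon inclusion through a logit-linear link,
  with junction read counts and an anti-correlated miRNA.
* ``generate_emt_experiment`` — a two-condition replicated design (e.g.
  epithelial vs mesenchymal cells) with planted ΔPSI effects.
* ``generate_clip_profiles`` — CLIP peaks placed direction-specifically
  around regulated exons (upstream-intron 3'ss window for exons the
  regulator skips, downstream intron for exons it includes), each true
  peak carrying the ACUAAC motif at its summit, over a uniform background.
* ``generate_target_evidence`` — multi-cohort expression/miRNA matrices,
  fold-change tables and seed-site/CLIP flags in which planted target
  genes satisfy every evidence source and decoys fail at least one.

Model of inclusion.  For a responsive event ``e`` in sample ``s``::

    logit(PSI_es) = alpha_e + beta_e * z_s + eps_es,   eps ~ N(0, sigma)

where ``z_s`` is the standardized log-expression of the regulator (exactly
standard normal by construction, and monotone in raw expression, so decile
membership is unaffected by the log).  Junction reads: the event's total
junction coverage is negative-binomial; an including isoform carries two
inclusion junctions and a skipping isoform one skipping junction, so reads
split multinomially with probabilities ``(psi, psi, 1-psi)/(1+psi)``.
Under this model the 2·skip-denominator PSI estimator is consistent.

Planted effect sizes.  ``SimulationConfig.effect_logit`` fixes a common
logit shift β; when it is ``None`` (the default) each responsive event's β
is solved numerically so that the *analytic* top/bottom-decile PSI
contrast (or, for the two-condition experiment, the direct PSI shift)
equals ``±target_delta_psi`` given that event's baseline and the noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtri

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "analytic_decile_delta",
    "effect_for_decile_delta",
    "make_event_table",
    "generate_cohort",
    "generate_emt_experiment",
    "generate_clip_profiles",
    "generate_target_evidence",
]

REGULATOR = "QKI"
MIRNA = "miR-200c"
MOTIF = "ACUAAC"

# synthetic genome geometry (per-event gene cassette, all on one chromosome)
_GENE_SPAN = 10_000
_EXON_LEN = 200
_ALT_LEN = 150
_INTRON_LEN = 1_000
_ORIGIN = 5_000


class ParameterError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the conditions of the recovery study the package is
    validated on: 500 samples, 200 cassette events of which 50 respond to
    the regulator with a planted decile contrast of |ΔPSI| = 0.35, mean
    junction coverage 50 with negative-binomial dispersion 5, logit-scale
    sample noise 0.4, miRNA-regulator Pearson r = -0.6, seven cohorts,
    three replicates per condition.
    """

    n_samples: int = 500
    n_events: int = 200
    n_responsive_events: int = 50
    effect_logit: float | None = None
    target_delta_psi: float = 0.35
    baseline_logit_range: tuple[float, float] = (-1.5, 1.5)
    mean_junction_coverage: float = 50.0
    coverage_dispersion: float = 5.0
    psi_noise_sd: float = 0.4
    mirna_anticorrelation: float = -0.6
    n_cancers: int = 7
    replicates_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_events, self.n_cancers,
               self.replicates_per_condition) < 1:
            raise ParameterError("all counts must be >= 1")
        if not 0 <= self.n_responsive_events <= self.n_events:
            raise ParameterError("n_responsive_events must be in [0, n_events]")
        if self.mean_junction_coverage <= 0 or self.coverage_dispersion <= 0:
            raise ParameterError("coverage parameters must be > 0")
        if self.psi_noise_sd < 0:
            raise ParameterError("psi_noise_sd must be >= 0")
        if not -1.0 <= self.mirna_anticorrelation <= 0.0:
            raise ParameterError("mirna_anticorrelation must be in [-1, 0]")
        if not 0.0 < self.target_delta_psi < 1.0:
            raise ParameterError("target_delta_psi must be in (0, 1)")
        lo, hi = self.baseline_logit_range
        if lo > hi:
            raise ParameterError("baseline_logit_range must be (lo, hi)")


@dataclass
class GroundTruth:
    """What was planted: responsive events, their effects and binding sides."""

    responsive_event_ids: set[str] = field(default_factory=set)
    true_delta_psi: dict[str, float] = field(default_factory=dict)
    true_binding_side: dict[str, str] = field(default_factory=dict)
    planted_target_genes: set[str] = field(default_factory=set)
    latent_psi: pd.DataFrame | None = None  # generating PSI, for recovery tests

    def to_frame(self) -> pd.DataFrame:
        events = sorted(self.true_delta_psi)
        return pd.DataFrame(
            {
                "event_id": events,
                "responsive": [e in self.responsive_event_ids for e in events],
                "true_delta_psi": [self.true_delta_psi[e] for e in events],
                "true_binding_side": [
                    self.true_binding_side.get(e, "none") for e in events
                ],
            }
        )


# ---------------------------------------------------------------------------
# analytic decile contrast under the logit-normal link

def _quad_nodes(n: int = 48) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x, w = leggauss(n)
    h, hw = hermgauss(n)
    return x, w / 2.0, h, hw / np.sqrt(np.pi)


def _decile_mean(alpha: float, beta: float, noise_sd: float,
                 lo_u: float, hi_u: float,
                 nodes: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]) -> float:
    x, wz, h, wh = nodes
    u = lo_u + (hi_u - lo_u) * (x + 1.0) / 2.0
    z = ndtri(u)
    arg = alpha + beta * z[:, None] + np.sqrt(2.0) * noise_sd * h[None, :]
    return float(wz @ expit(arg) @ wh)


def analytic_decile_delta(alpha: float, beta: float, noise_sd: float,
                          fraction: float = 0.10) -> float:
    """Expected top-minus-bottom decile PSI contrast implied by the link.

    Integrates E[expit(alpha + beta z + eps)] over z restricted to the top
    (resp. bottom) ``fraction`` of N(0,1) and eps ~ N(0, noise_sd), by
    Gauss-Legendre x Gauss-Hermite quadrature.
    """
    nodes = _quad_nodes()
    hi = _decile_mean(alpha, beta, noise_sd, 1.0 - fraction, 1.0, nodes)
    lo = _decile_mean(alpha, beta, noise_sd, 0.0, fraction, nodes)
    return hi - lo


def effect_for_decile_delta(target: float, alpha: float, noise_sd: float,
                            fraction: float = 0.10) -> float:
    """Solve for the logit shift beta whose analytic decile contrast is ``target``.

    ``target`` may be negative; the solved beta carries its sign.
    """
    if target == 0.0:
        return 0.0
    mag = abs(target)
    f = lambda b: analytic_decile_delta(alpha, b, noise_sd, fraction) - mag
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 512:
            raise ParameterError(
                f"decile contrast {mag} unreachable at alpha={alpha}"
            )
    beta = brentq(f, 0.0, hi, xtol=1e-10)
    return float(np.copysign(beta, target))


# ---------------------------------------------------------------------------
# event geometry

def make_event_table(n_events: int) -> pd.DataFrame:
    """Lay out one skipped-exon cassette per gene along a synthetic chromosome.

    Coordinates are genomic 0-based half-open; exon columns are
    transcript-sense (for - strand genes the upstream exon is the
    genomic-right one).  Strands alternate so strand handling is always
    exercised.
    """
    rows = []
    for i in range(n_events):
        o = _ORIGIN + i * _GENE_SPAN
        e1 = (o, o + _EXON_LEN)
        alt = (e1[1] + _INTRON_LEN, e1[1] + _INTRON_LEN + _ALT_LEN)
        e2 = (alt[1] + _INTRON_LEN, alt[1] + _INTRON_LEN + _EXON_LEN)
        strand = "+" if i % 2 == 0 else "-"
        up, dn = (e1, e2) if strand == "+" else (e2, e1)
        rows.append(
            (f"SE{i:04d}", f"GENE{i:04d}", "chr1", strand,
             up[0], up[1], alt[0], alt[1], dn[0], dn[1])
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene", "chrom", "strand",
                 "up_start", "up_end", "alt_start", "alt_end",
                 "dn_start", "dn_end"],
    )


def event_junctions(event: pd.Series) -> dict[str, tuple[str, int, int]]:
    """Genomic intron spans (0-based half-open) of an event's three junctions."""
    g_left = min(event.up_start, event.dn_start)
    g_left_end = min(event.up_end, event.dn_end)
    g_right = max(event.up_start, event.dn_start)
    chrom = event.chrom
    return {
        "inc_up": (chrom, g_left_end, event.alt_start),
        "inc_down": (chrom, event.alt_end, g_right),
        "skip": (chrom, g_left_end, g_right),
    }


# ---------------------------------------------------------------------------
# count sampling

def _negbin_totals(rng: np.random.Generator, mean: float, size: float,
                   shape: tuple[int, ...]) -> np.ndarray:
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=shape)


def _split_junction_reads(rng: np.random.Generator, totals: np.ndarray,
                          psi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multinomial split of junction reads given transcript-level PSI."""
    p_inc = 2.0 * psi / (1.0 + psi)
    inc = rng.binomial(totals, p_inc)
    up = rng.binomial(inc, 0.5)
    down = inc - up
    skip = totals - inc
    return up, down, skip


def _pick_effects(cfg: SimulationConfig, rng: np.random.Generator,
                  alphas: np.ndarray, responsive: np.ndarray,
                  mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-event beta and true effect; sign alternates over responsive events."""
    n = len(alphas)
    betas = np.zeros(n)
    true_delta = np.zeros(n)
    signs = np.where(np.arange(responsive.sum()) % 2 == 0, 1.0, -1.0)
    rng.shuffle(signs)
    for k, idx in enumerate(np.flatnonzero(responsive)):
        a = alphas[idx]
        s = signs[k]
        if cfg.effect_logit is not None:
            b = s * abs(cfg.effect_logit)
            if mode == "decile":
                d = analytic_decile_delta(a, b, cfg.psi_noise_sd)
            else:
                d = float(expit(a + b) - expit(a))
        else:
            d = s * cfg.target_delta_psi
            if mode == "decile":
                b = effect_for_decile_delta(d, a, cfg.psi_noise_sd)
            else:
                # clamp the baseline so the planted shift fits inside (0, 1)
                lo_a = float(logit(0.01 + max(0.0, -d)))
                hi_a = float(logit(0.99 - max(0.0, d)))
                a = float(np.clip(a, lo_a, hi_a))
                alphas[idx] = a
                b = float(logit(expit(a) + d) - a)
        betas[idx] = b
        true_delta[idx] = d
    return betas, true_delta


def _truth_from_effects(events: pd.DataFrame, responsive: np.ndarray,
                        true_delta: np.ndarray) -> GroundTruth:
    truth = GroundTruth()
    for i, ev in enumerate(events.event_id):
        truth.true_delta_psi[ev] = float(true_delta[i])
        if responsive[i]:
            truth.responsive_event_ids.add(ev)
            # regulator-high means included (delta > 0): binding downstream
            # intron; regulator promotes skipping (delta < 0): binding in the
            # 100 nt upstream of the cassette 3'ss.
            side = "downstream_intron" if true_delta[i] > 0 else "upstream_intron"
            truth.true_binding_side[ev] = side
        else:
            truth.true_binding_side[ev] = "none"
    return truth


def _long_junction_table(events: pd.DataFrame, samples: list[str],
                         up: np.ndarray, down: np.ndarray,
                         skip: np.ndarray) -> pd.DataFrame:
    """Long-form junction table (one row per junction per sample)."""
    frames = []
    counts = {"inc_up": up, "inc_down": down, "skip": skip}
    n_s = len(samples)
    for _, ev in events.iterrows():
        juncs = event_junctions(ev)
        i = events.index.get_loc(ev.name)
        for role, (chrom, a, b) in juncs.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": a,
                        "end": b,
                        "strand": ev.strand,
                        "count": counts[role][i],
                        "sample": samples,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(config: SimulationConfig) -> tuple[
    pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth
]:
    """Simulate one cohort: expression, miRNA, junction counts, events, truth.

    Returns ``(expression, mirna, junctions, events, truth)``.  Expression
    matrices are on the log2 scale (raw expression is lognormal); the
    junction table is long-form with one row per junction per sample.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    events = make_event_table(cfg.n_events)

    z = rng.standard_normal(cfg.n_samples)
    regulator_log2 = 5.0 + z  # raw expression = 2**(.) ~ lognormal
    r = cfg.mirna_anticorrelation
    mirna_vals = 8.0 + r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(cfg.n_samples)

    decoys = rng.standard_normal((5, cfg.n_samples)) + 6.0
    expression = pd.DataFrame(
        np.vstack([regulator_log2, decoys]),
        index=[REGULATOR] + [f"CTRL{i}" for i in range(5)],
        columns=samples,
    )
    mirna = pd.DataFrame([mirna_vals], index=[MIRNA], columns=samples)

    responsive = np.zeros(cfg.n_events, dtype=bool)
    responsive[rng.choice(cfg.n_events, cfg.n_responsive_events, replace=False)] = True
    lo, hi = cfg.baseline_logit_range
    alphas = rng.uniform(lo, hi, cfg.n_events)
    betas, true_delta = _pick_effects(cfg, rng, alphas, responsive, mode="decile")

    eps = rng.normal(0.0, cfg.psi_noise_sd, (cfg.n_events, cfg.n_samples))
    psi = expit(alphas[:, None] + betas[:, None] * z[None, :] + eps)
    totals = _negbin_totals(
        rng, cfg.mean_junction_coverage, cfg.coverage_dispersion,
        (cfg.n_events, cfg.n_samples),
    )
    up, down, skip = _split_junction_reads(rng, totals, psi)
    junctions = _long_junction_table(events, samples, up, down, skip)
    truth = _truth_from_effects(events, responsive, true_delta)
    truth.latent_psi = pd.DataFrame(psi, index=events.event_id.tolist(),
                                    columns=samples)
    return expression, mirna, junctions, events, truth


def generate_emt_experiment(config: SimulationConfig) -> tuple[
    pd.DataFrame, pd.DataFrame, GroundTruth
]:
    """Two-condition replicated junction counts with planted ΔPSI effects.

    Returns ``(counts, events, truth)``.  ``counts`` has one row per event
    junction (role inc_up/inc_down/skip with genomic coordinates) and one
    count column per replicate, named ``A_1..A_m, B_1..B_m``.
    ``true_delta_psi`` is mean(B) - mean(A) on the PSI scale.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    events = make_event_table(cfg.n_events)
    m = cfg.replicates_per_condition

    responsive = np.zeros(cfg.n_events, dtype=bool)
    responsive[rng.choice(cfg.n_events, cfg.n_responsive_events, replace=False)] = True
    lo, hi = cfg.baseline_logit_range
    alphas = rng.uniform(lo, hi, cfg.n_events)
    betas, true_delta = _pick_effects(cfg, rng, alphas, responsive, mode="shift")

    cols = [f"A_{j + 1}" for j in range(m)] + [f"B_{j + 1}" for j in range(m)]
    base = np.concatenate(
        [np.tile(alphas[:, None], (1, m)),
         np.tile((alphas + betas)[:, None], (1, m))], axis=1
    )
    eps = rng.normal(0.0, cfg.psi_noise_sd, base.shape)
    psi = expit(base + eps)
    totals = _negbin_totals(
        rng, cfg.mean_junction_coverage, cfg.coverage_dispersion, base.shape
    )
    up, down, skip = _split_junction_reads(rng, totals, psi)

    rows = []
    for i, ev in events.iterrows():
        juncs = event_junctions(ev)
        for role, (chrom, a, b) in juncs.items():
            cnt = {"inc_up": up, "inc_down": down, "skip": skip}[role][i]
            rows.append(
                [ev.event_id, role, chrom, a, b, ev.strand, *cnt.tolist()]
            )
    counts = pd.DataFrame(
        rows, columns=["event_id", "junction", "chrom", "start", "end", "strand", *cols]
    )
    truth = _truth_from_effects(events, responsive, true_delta)
    return counts, events, truth


# ---------------------------------------------------------------------------
# CLIP peaks

_PEAK_WIDTH = 40
_PLACEMENT_WINDOW = 100  # nt from the relevant splice site


def _binding_window(ev: pd.Series, side: str) -> tuple[int, int]:
    """Genomic interval in which a true peak's summit may fall."""
    if side == "exon":
        return int(ev.alt_start), int(ev.alt_end)
    if side == "upstream_intron":
        # within 100 nt upstream of the cassette exon's 3' splice site
        if ev.strand == "+":
            return int(ev.alt_start) - _PLACEMENT_WINDOW, int(ev.alt_start)
        return int(ev.alt_end), int(ev.alt_end) + _PLACEMENT_WINDOW
    if side == "downstream_intron":
        # within the first 100 nt of the downstream intron (past the 5'ss)
        if ev.strand == "+":
            return int(ev.alt_end), int(ev.alt_end) + _PLACEMENT_WINDOW
        return int(ev.alt_start) - _PLACEMENT_WINDOW, int(ev.alt_start)
    raise ValueError(f"unknown binding side {side!r}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])


def _seq_with_motif(rng: np.random.Generator, length: int, summit_off: int) -> str:
    seq = list(_random_seq(rng, length))
    start = int(np.clip(summit_off, 0, length - len(MOTIF)))
    seq[start:start + len(MOTIF)] = list(MOTIF)
    return "".join(seq)


PEAK_COLUMNS = ["chrom", "start", "end", "name", "height", "strand",
                "summit", "sequence", "kind"]


def generate_clip_profiles(events: pd.DataFrame, truth: GroundTruth,
                           peak_height_mean: float = 10.0,
                           background_rate: float = 2e-4,
                           seed: int = 0) -> pd.DataFrame:
    """Place CLIP peaks by each event's planted binding side, over background.

    True peaks sit with their summit inside the side-specific window
    (within 100 nt of the relevant splice site) and carry the ACUAAC motif
    at the summit; background peaks are uniform over the simulated span at
    ``background_rate`` peaks per nucleotide, with random sequence.
    Sequences are stored 5'->3' on the peak's own strand.
    """
    rng = np.random.default_rng(seed)
    required = {"event_id", "chrom", "strand", "alt_start", "alt_end"}
    if not required.issubset(events.columns):
        raise ValueError(f"event table lacks columns {required - set(events.columns)}")
    rows = []
    for _, ev in events.iterrows():
        side = truth.true_binding_side.get(ev.event_id, "none")
        if side == "none":
            continue
        n_pk = 1 + rng.poisson(1.0)
        w0, w1 = _binding_window(ev, side)
        for k in range(n_pk):
            summit = int(rng.integers(w0, w1))
            start = summit - _PEAK_WIDTH // 2
            end = start + _PEAK_WIDTH
            height = float(rng.gamma(2.0, peak_height_mean / 2.0))
            off = summit - start if ev.strand == "+" else end - 1 - summit
            seq = _seq_with_motif(rng, _PEAK_WIDTH, off)
            rows.append(
                (ev.chrom, start, end, f"peak_{ev.event_id}_{k}", height,
                 ev.strand, summit, seq, "signal")
            )
    if len(events) and background_rate > 0:
        lo = int(events[["up_start", "dn_start"]].min().min())
        hi = int(events[["up_end", "dn_end"]].max().max())
        n_bg = rng.poisson(background_rate * (hi - lo))
        for k in range(n_bg):
            start = int(rng.integers(lo, hi - _PEAK_WIDTH))
            end = start + _PEAK_WIDTH
            summit = start + _PEAK_WIDTH // 2
            height = float(rng.gamma(2.0, peak_height_mean / 2.0))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                ("chr1", start, end, f"bg_{k}", height, strand, summit,
                 _random_seq(rng, _PEAK_WIDTH), "background")
            )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


# ---------------------------------------------------------------------------
# target-discovery evidence

FOLD_SOURCES = ("mdck_emt", "hmle_emt", "mir200_transfection")
FLAG_SOURCES = ("targetscan_site", "ago_clip_peak")
_DECOY_R_SHRINK = 0.7  # decoy correlations are weaker than planted ones


def generate_target_evidence(
    config: SimulationConfig,
    planted_targets: set[str],
    seed: int | None = None,
    n_genes: int = 1000,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.Series],
           dict[str, pd.Series], pd.DataFrame, GroundTruth]:
    """Evidence inputs for the target-discovery pipeline, with planted truth.

    Returns ``(expression, mirna, fold_changes, flags, truth)`` where
    ``expression``/``mirna`` map clinical dataset name to matrix/vector,
    ``fold_changes`` maps experimental dataset to linear fold-change
    Series, and ``flags`` holds the seed-site and Ago-CLIP booleans.
    Planted targets pass every source (anti-correlation at
    ``config.mirna_anticorrelation``, folds past all thresholds, both
    flags); each decoy fails at least one source, and decoy correlations,
    when present, are shrunk so no decoy is more consistent than a
    planted target.
    """
    if not planted_targets:
        raise ParameterError("planted_targets must be nonempty")
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    planted = sorted(planted_targets)
    n_decoys = n_genes - len(planted)
    if n_decoys < 0:
        raise ParameterError("n_genes smaller than number of planted targets")
    genes = planted + [f"DECOY{i:04d}" for i in range(n_decoys)]
    datasets = [f"cohort{c + 1}" for c in range(cfg.n_cancers)]

    n_sources = len(FOLD_SOURCES) + len(FLAG_SOURCES) + len(datasets)
    passes = rng.random((len(genes), n_sources)) < 0.5
    passes[: len(planted), :] = True
    all_pass = passes.all(axis=1)
    all_pass[: len(planted)] = False
    for i in np.flatnonzero(all_pass):  # decoys must fail somewhere
        passes[i, rng.integers(0, n_sources)] = False

    col = {s: j for j, s in enumerate(list(FOLD_SOURCES) + list(FLAG_SOURCES))}
    ds_col = {d: len(col) + j for j, d in enumerate(datasets)}

    folds: dict[str, pd.Series] = {}
    spec = {
        "mdck_emt": ((1.6, 3.0), (0.6, 1.45)),
        "hmle_emt": ((1.4, 2.5), (0.6, 1.25)),
        "mir200_transfection": ((0.3, 0.64), (0.72, 1.8)),
    }
    for name in FOLD_SOURCES:
        ok_rng, bad_rng = spec[name]
        vals = np.where(
            passes[:, col[name]],
            rng.uniform(*ok_rng, len(genes)),
            rng.uniform(*bad_rng, len(genes)),
        )
        folds[name] = pd.Series(vals, index=genes, name=name)

    flags = pd.DataFrame(
        {name: passes[:, col[name]] for name in FLAG_SOURCES}, index=genes
    )

    r = cfg.mirna_anticorrelation
    expression: dict[str, pd.DataFrame] = {}
    mirna: dict[str, pd.Series] = {}
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    for d in datasets:
        m = rng.standard_normal(cfg.n_samples)
        noise = rng.standard_normal((len(genes), cfg.n_samples))
        r_gene = np.where(
            passes[:, ds_col[d]],
            np.where(np.arange(len(genes)) < len(planted), r, r * _DECOY_R_SHRINK),
            0.0,
        )
        x = r_gene[:, None] * m[None, :] + np.sqrt(1.0 - r_gene**2)[:, None] * noise
        expression[d] = pd.DataFrame(x + 8.0, index=genes, columns=samples)
        mirna[d] = pd.Series(m + 8.0, index=samples, name=MIRNA)

    truth = GroundTruth(planted_target_genes=set(planted))
    return expression, mirna, folds, flags, truth
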