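"""Positional CLIP "splicing maps" around regulated exons, motif statistics
and genomic-region annotation of peaks.

A splicing map summarizes where an RNA-binding protein sits relative to
the exons it regulates: for each event in a group (e.g. exons skipped or
included upon regulator knockdown, or a non-regulated background set) the
peak height covering every position of a standardized window around the
cassette is recorded, the per-position mean over events is the profile,
and a one-sided rank test per position gives enrichment of the group over
the background.  The window concatenates, in transcript orientation:

    [upstream exon | intron 5' flank | intron 3' flank |
     cassette exon | intron 5' flank | intron 3' flank | downstream exon]

with exon bodies scaled to ``exon_bins`` positions and intronic flanks of
``flank`` nt anchored at the splice sites.  Minus-strand events are
mirrored so position runs 5'->3' along the transcript for every event.

Peak height contributes over every base the peak covers (plateau model),
not as a point mass at the summit.  Per-position p-values are left
uncorrected across positions — the profile is descriptive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact, mannwhitneyu

from .io import DataError

__all__ = [
    "SplicingMapProfile",
    "MotifStats",
    "window_layout",
    "build_splicing_map",
    "position_enrichment",
    "motif_enrichment",
    "motif_positional_profile",
    "annotate_peak_regions",
    "REGION_CATEGORIES",
]

log = logging.getLogger(__name__)

DEFAULT_FLANK = 250
DEFAULT_EXON_BINS = 50
P_FLOOR = 1e-300

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}

_COMPLEMENT = str.maketrans("ACGUT", "UGCAA")


class SizeError(ValueError):
    """Too few events/peaks for the requested map."""


def _motif_regex(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(_IUPAC[c] for c in motif.upper()))
    except KeyError as e:
        raise DataError(f"non-IUPAC motif character {e.args[0]!r}") from None


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp(seq: str) -> str:
    return _normalize_seq(seq).translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# window geometry

@dataclass
class WindowLayout:
    """Segment boundaries of the concatenated splicing-map coordinate system."""

    flank: int
    exon_bins: int

    @property
    def segment_lengths(self) -> list[int]:
        f, e = self.flank, self.exon_bins
        return [e, f, f, e, f, f, e]

    @property
    def total(self) -> int:
        return 3 * self.exon_bins + 4 * self.flank

    @property
    def offsets(self) -> list[int]:
        out, acc = [], 0
        for seg in self.segment_lengths:
            out.append(acc)
            acc += seg
        return out

    @property
    def alt_3ss(self) -> int:
        """Index of the cassette exon's 3' splice site (first exon-body bin)."""
        return self.exon_bins + 2 * self.flank

    @property
    def downstream_intron(self) -> tuple[int, int]:
        """Index span of the intron downstream of the cassette exon."""
        start = 2 * self.exon_bins + 2 * self.flank
        return start, start + 2 * self.flank


def window_layout(flank: int = DEFAULT_FLANK,
                  exon_bins: int = DEFAULT_EXON_BINS) -> WindowLayout:
    return WindowLayout(flank=flank, exon_bins=exon_bins)


def _peak_trees(peaks: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in peaks.itertuples(index=False):
        key = (row.chrom, row.strand)
        trees.setdefault(key, IntervalTree()).addi(row.start, row.end, row.height)
    return trees


def _coverage(trees, chrom: str, strand: str, lo: int, hi: int) -> np.ndarray:
    """Summed peak height per base over genomic [lo, hi), strand-matched."""
    cov = np.zeros(hi - lo)
    if hi <= lo:
        return cov
    for st in (strand, "."):
        tree = trees.get((chrom, st))
        if tree is None:
            continue
        for iv in tree.overlap(lo, hi):
            a, b = max(iv.begin, lo), min(iv.end, hi)
            cov[a - lo:b - lo] += iv.data
    return cov


def _bin_exon(arr: np.ndarray, bins: int) -> np.ndarray:
    if len(arr) == bins:
        return arr
    return np.interp(np.linspace(0, len(arr) - 1, bins), np.arange(len(arr)), arr)


def _event_window_coverage(trees, ev: pd.Series, layout: WindowLayout) -> np.ndarray:
    """Coverage over the standardized window, in transcript orientation.

    Segment roles: ``exon`` bodies are rescaled to ``exon_bins``;
    ``flank5`` is an intron's first ``flank`` nt (anchored at the 5'ss,
    zero-padded at its far end when the intron is shorter) and ``flank3``
    its last ``flank`` nt (anchored at the 3'ss, padded at the near end).
    """
    f = layout.flank
    chrom, strand = ev.chrom, ev.strand
    if strand == "+":
        segs = [
            ("exon", ev.up_start, ev.up_end),
            ("flank5", ev.up_end, min(ev.up_end + f, ev.alt_start)),
            ("flank3", max(ev.alt_start - f, ev.up_end), ev.alt_start),
            ("exon", ev.alt_start, ev.alt_end),
            ("flank5", ev.alt_end, min(ev.alt_end + f, ev.dn_start)),
            ("flank3", max(ev.dn_start - f, ev.alt_end), ev.dn_start),
            ("exon", ev.dn_start, ev.dn_end),
        ]
    else:
        # transcript order runs right-to-left genomically
        segs = [
            ("exon", ev.up_start, ev.up_end),
            ("flank5", max(ev.up_start - f, ev.alt_end), ev.up_start),
            ("flank3", ev.alt_end, min(ev.alt_end + f, ev.up_start)),
            ("exon", ev.alt_start, ev.alt_end),
            ("flank5", max(ev.alt_start - f, ev.dn_end), ev.alt_start),
            ("flank3", ev.dn_end, min(ev.dn_end + f, ev.alt_start)),
            ("exon", ev.dn_start, ev.dn_end),
        ]
    parts = []
    for kind, lo, hi in segs:
        cov = _coverage(trees, chrom, strand, int(lo), int(hi))
        if strand == "-":
            cov = cov[::-1]
        if kind == "exon":
            parts.append(_bin_exon(cov, layout.exon_bins))
        else:
            pad = f - len(cov)
            if pad > 0:  # intron shorter than the flank: zero-fill the gap
                cov = (np.concatenate([cov, np.zeros(pad)]) if kind == "flank5"
                       else np.concatenate([np.zeros(pad), cov]))
            parts.append(cov)
    return np.concatenate(parts)


@dataclass
class SplicingMapProfile:
    """Per-position mean CLIP coverage around one group of events."""

    label: str
    layout: WindowLayout
    mean_height: np.ndarray
    event_matrix: np.ndarray  # n_events x window length
    n_events: int
    enrichment_neg_log10_p: np.ndarray | None = None
    low_confidence: bool = False


def build_splicing_map(peaks: pd.DataFrame,
                       events_by_group: Mapping[str, pd.DataFrame],
                       flank: int = DEFAULT_FLANK,
                       exon_bins: int = DEFAULT_EXON_BINS
                       ) -> dict[str, SplicingMapProfile]:
    """Per-group positional coverage profiles around cassette exons.

    ``events_by_group`` maps a group label (e.g. ``skipped_on_kd``,
    ``included_on_kd``, ``background``) to an event table; every event
    needs resolvable coordinates.  Minus-strand events are mirrored into
    transcript orientation.
    """
    layout = window_layout(flank, exon_bins)
    trees = _peak_trees(peaks)
    profiles = {}
    for label, events in events_by_group.items():
        if len(events) == 0:
            raise SizeError(f"group {label!r} is empty")
        mat = np.vstack(
            [_event_window_coverage(trees, ev, layout)
             for _, ev in events.iterrows()]
        )
        profiles[label] = SplicingMapProfile(
            label=label, layout=layout, mean_height=mat.mean(axis=0),
            event_matrix=mat, n_events=len(events),
        )
    return profiles


def position_enrichment(group: SplicingMapProfile,
                        background: SplicingMapProfile
                        ) -> np.ndarray:
    """Per-position -log10(p), one-sided Mann-Whitney U (group > background).

    Positions where all events in both groups are tied (typically zero
    coverage) get p = 1.  No correction across positions.  The result is
    stored on ``group.enrichment_neg_log10_p``; groups with a single
    event, or backgrounds of fewer than 5 events, set ``low_confidence``.
    """
    g, b = group.event_matrix, background.event_matrix
    if background.n_events < 5:
        log.warning("background has %d (<5) events: wide-variance profile",
                    background.n_events)
        group.low_confidence = True
    if group.n_events < 2:
        log.warning("group %s has a single event: all positions low-confidence",
                    group.label)
        group.low_confidence = True
    with np.errstate(invalid="ignore", divide="ignore"):
        res = mannwhitneyu(g, b, axis=0, alternative="greater",
                           method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    tied = (g.std(axis=0) == 0) & (b.std(axis=0) == 0) & (
        g.mean(axis=0) == b.mean(axis=0)
    )
    p[np.isnan(p) | tied] = 1.0
    p = np.clip(p, P_FLOOR, 1.0)
    group.enrichment_neg_log10_p = -np.log10(p)
    return group.enrichment_neg_log10_p


# ---------------------------------------------------------------------------
# motifs

@dataclass
class MotifStats:
    motif: str
    peak_hit_fraction: float
    background_hit_fraction: float
    enrichment_p: float
    n_peaks: int
    n_background: int


def motif_enrichment(peak_seqs: Sequence[str], background_seqs: Sequence[str],
                     motif: str = "ACUAAC") -> MotifStats:
    """One-sided Fisher exact test for motif presence in peaks vs background."""
    if not len(peak_seqs) or not len(background_seqs):
        raise SizeError("empty sequence set")
    rx = _motif_regex(motif)
    hit = lambda seqs: sum(bool(rx.search(_normalize_seq(s))) for s in seqs)
    a, b = hit(peak_seqs), hit(background_seqs)
    table = [[a, len(peak_seqs) - a], [b, len(background_seqs) - b]]
    _, p = fisher_exact(table, alternative="greater")
    return MotifStats(
        motif=motif,
        peak_hit_fraction=a / len(peak_seqs),
        background_hit_fraction=b / len(background_seqs),
        enrichment_p=float(p),
        n_peaks=len(peak_seqs),
        n_background=len(background_seqs),
    )


def motif_positional_profile(peaks: pd.DataFrame, motif: str = "ACUAAC"
                             ) -> dict[str, object]:
    """Motif-start offsets relative to the peak summit, sense vs antisense.

    Peak sequences are 5'->3' on the peak's own strand; the summit offset
    within the sequence is derived from the genomic summit (mirrored for
    minus-strand peaks).  The antisense (reverse-complement) histogram is
    the empirical background.  Peaks without a sequence are excluded and
    counted in the diagnostics.
    """
    rx = _motif_regex(motif)
    sense, antisense = [], []
    n_missing = 0
    for row in peaks.itertuples(index=False):
        seq = getattr(row, "sequence", None)
        if not isinstance(seq, str) or not seq:
            n_missing += 1
            continue
        off = (row.summit - row.start if row.strand != "-"
               else row.end - 1 - row.summit)
        s = _normalize_seq(seq)
        sense.extend(m.start() - off for m in rx.finditer(s))
        rc = _revcomp(seq)
        off_rc = len(seq) - 1 - off
        antisense.extend(m.start() - off_rc for m in rx.finditer(rc))
    return {
        "sense": np.array(sense, dtype=int),
        "antisense": np.array(antisense, dtype=int),
        "n_no_sequence": n_missing,
    }


# ---------------------------------------------------------------------------
# genomic-region annotation

REGION_CATEGORIES = ["CDS", "5'UTR", "3'UTR", "ncRNA", "intron", "intergenic"]

_UTR_FEATURES = {"five_prime_utr": "5'UTR", "three_prime_utr": "3'UTR"}


def annotate_peak_regions(peaks: pd.DataFrame, annotation: pd.DataFrame
                          ) -> tuple[pd.Series, pd.Series]:
    """Assign each peak to a genomic region by its summit.

    Precedence: CDS > UTR > ncRNA > intron > intergenic.  ``annotation``
    is a frame from :func:`qkisplice.io.read_gtf`.  Returns
    ``(proportions, assignments)``; proportions cover all categories and
    sum to 1.
    """
    if len(peaks) == 0:
        raise SizeError("empty peak set")
    needed = {"chrom", "feature", "start", "end", "gene_id"}
    if not needed.issubset(annotation.columns):
        raise DataError(f"annotation lacks columns {needed - set(annotation.columns)}")

    trees: dict[str, dict[str, IntervalTree]] = {}

    def add(cat: str, chrom: str, start: int, end: int) -> None:
        if end > start:
            trees.setdefault(cat, {}).setdefault(chrom, IntervalTree()).addi(
                start, end
            )

    for row in annotation.itertuples(index=False):
        if row.feature == "CDS":
            add("CDS", row.chrom, row.start, row.end)
        elif row.feature in _UTR_FEATURES:
            add(_UTR_FEATURES[row.feature], row.chrom, row.start, row.end)
        elif row.feature == "exon" and row.gene_biotype not in ("protein_coding", ""):
            add("ncRNA", row.chrom, row.start, row.end)

    gene_span = annotation.groupby(["gene_id", "chrom"]).agg(
        start=("start", "min"), end=("end", "max")
    ).reset_index()
    for row in gene_span.itertuples(index=False):
        add("gene", row.chrom, row.start, row.end)

    order = ["CDS", "5'UTR", "3'UTR", "ncRNA"]
    cats = []
    for row in peaks.itertuples(index=False):
        pos = int(row.summit)
        assigned = None
        for cat in order:
            t = trees.get(cat, {}).get(row.chrom)
            if t is not None and t.overlaps(pos):
                assigned = cat
                break
        if assigned is None:
            t = trees.get("gene", {}).get(row.chrom)
            assigned = "intron" if t is not None and t.overlaps(pos) else "intergenic"
        cats.append(assigned)
    assignments = pd.Series(cats, index=peaks.index, name="region")
    proportions = (
        assignments.value_counts(normalize=True)
        .reindex(REGION_CATEGORIES, fill_value=0.0)
    )
    return proportions, assignments
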