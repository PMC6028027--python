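"""Percent-spliced-in (PSI) from splice-junction read counts.

Two quantifications are provided:

* ``event_psi`` — the skipped-exon event form.  An including isoform
  produces reads on two inclusion junctions while a skipping isoform
  produces reads on one skipping junction, so the estimator uses a
  doubled skip count::

      PSI = (inc_up + inc_down) / (inc_up + inc_down + 2 * skip)

  which balances one inclusion "event" against one skipping "event".
* ``junction_psi_both_orientations`` — the per-junction form: every
  junction's count as a fraction of all counts sharing its donor site,
  and again of all counts sharing its acceptor site.

A PSI value is *missing* (NaN) rather than zero when the informative read
total is below ``min_coverage``; zero-coverage cells otherwise masquerade
as confidently excluded exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError
from .simulate import event_junctions

__all__ = [
    "SpliceEvent",
    "PsiMatrix",
    "event_psi",
    "junction_psi_both_orientations",
    "build_psi_matrix",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 10


@dataclass(frozen=True)
class SpliceEvent:
    """A skipped-exon event: three exons, two inclusion junctions, one skip.

    Exon intervals are genomic 0-based half-open; ``upstream_exon`` and
    ``downstream_exon`` are transcript-sense (mirrored on the - strand).
    """

    event_id: str
    gene: str
    chrom: str
    strand: str
    upstream_exon: tuple[int, int]
    alt_exon: tuple[int, int]
    downstream_exon: tuple[int, int]

    def __post_init__(self) -> None:
        for name in ("upstream_exon", "alt_exon", "downstream_exon"):
            a, b = getattr(self, name)
            if a >= b:
                raise DataError(f"{self.event_id}: {name} has start >= end")
        left, right = ((self.upstream_exon, self.downstream_exon)
                       if self.strand != "-"
                       else (self.downstream_exon, self.upstream_exon))
        if not left[1] <= self.alt_exon[0] or not self.alt_exon[1] <= right[0]:
            raise DataError(f"{self.event_id}: exons out of genomic order")

    @property
    def junctions(self) -> dict[str, tuple[str, int, int]]:
        """Intron spans of inc_up, inc_down and skip junctions."""
        row = pd.Series(
            {
                "chrom": self.chrom,
                "up_start": self.upstream_exon[0], "up_end": self.upstream_exon[1],
                "alt_start": self.alt_exon[0], "alt_end": self.alt_exon[1],
                "dn_start": self.downstream_exon[0], "dn_end": self.downstream_exon[1],
            }
        )
        return event_junctions(row)


@dataclass
class PsiMatrix:
    """Events x samples PSI with matching informative-read coverage."""

    psi: pd.DataFrame
    coverage: pd.DataFrame
    dropped: dict[str, str]  # event_id -> reason

    def __post_init__(self) -> None:
        if not self.psi.index.equals(self.coverage.index) or not (
            self.psi.columns.equals(self.coverage.columns)
        ):
            raise DataError("psi and coverage matrices are not aligned")

    def write(self, psi_path, coverage_path) -> None:
        self.psi.to_csv(psi_path, sep="\t")
        self.coverage.to_csv(coverage_path, sep="\t")


def event_psi(inc_up: int, inc_down: int, skip: int,
              min_coverage: int = DEFAULT_MIN_COVERAGE) -> float:
    """PSI of one event in one sample; NaN below the coverage threshold."""
    if min(inc_up, inc_down, skip) < 0:
        raise DataError("negative junction count")
    if inc_up + inc_down + skip < min_coverage:
        return float("nan")
    inc = inc_up + inc_down
    denom = inc + 2 * skip
    if denom == 0:
        return float("nan")
    return inc / denom


def junction_psi_both_orientations(junctions: pd.DataFrame,
                                   min_coverage: int = DEFAULT_MIN_COVERAGE
                                   ) -> pd.DataFrame:
    """Per-junction usage fractions at the shared donor and acceptor sites.

    ``junctions`` is one sample's table (chrom/start/end/count).  The
    donor-anchored PSI of junction j is count(j) over the summed counts of
    all junctions sharing j's intron start; acceptor-anchored uses the
    shared intron end.  Fractions are NaN where the shared-site total is
    below ``min_coverage``.
    """
    out = junctions.copy()
    donor_tot = out.groupby(["chrom", "start"])["count"].transform("sum")
    accep_tot = out.groupby(["chrom", "end"])["count"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["donor_psi"] = np.where(
            donor_tot >= max(min_coverage, 1), out["count"] / donor_tot, np.nan
        )
        out["acceptor_psi"] = np.where(
            accep_tot >= max(min_coverage, 1), out["count"] / accep_tot, np.nan
        )
    return out


def build_psi_matrix(junctions: pd.DataFrame, events: pd.DataFrame,
                     min_coverage: int = DEFAULT_MIN_COVERAGE) -> PsiMatrix:
    """Event x sample PSI matrix from a long junction table.

    An event whose junction coordinates never appear in the table (in any
    sample) is dropped with a diagnostic; a junction present in the table
    overall but absent for one sample is an observed zero for that sample
    (aligners omit zero-read junctions).
    """
    samples = sorted(junctions["sample"].unique())
    pivot = junctions.pivot_table(
        index=["chrom", "start", "end"], columns="sample", values="count",
        aggfunc="sum", fill_value=0,
    ).reindex(columns=samples, fill_value=0)

    psi_rows, cov_rows, kept, dropped = [], [], [], {}
    n_samples = len(samples)
    for _, ev in events.iterrows():
        juncs = event_junctions(ev)
        counts = {}
        n_found = 0
        for role, key in juncs.items():
            if key in pivot.index:
                counts[role] = pivot.loc[key].to_numpy(dtype=float)
                n_found += 1
            else:
                counts[role] = np.zeros(n_samples)
        if n_found == 0:
            dropped[ev.event_id] = "no junction of this event found in the table"
            continue
        inc = counts["inc_up"] + counts["inc_down"]
        informative = inc + counts["skip"]
        denom = inc + 2 * counts["skip"]
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(
                (informative >= min_coverage) & (denom > 0), inc / denom, np.nan
            )
        psi_rows.append(psi)
        cov_rows.append(informative)
        kept.append(ev.event_id)
    for ev_id, reason in dropped.items():
        log.warning("dropping event %s: %s", ev_id, reason)
    psi_df = pd.DataFrame(psi_rows, index=kept, columns=samples)
    cov_df = pd.DataFrame(cov_rows, index=kept, columns=samples)
    return PsiMatrix(psi=psi_df, coverage=cov_df, dropped=dropped)
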