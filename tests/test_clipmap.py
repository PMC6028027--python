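"""Splicing-map geometry, positional enrichment, motifs, region annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, fisher_exact, mannwhitneyu

from qkisplice.clipmap import (
    SizeError,
    annotate_peak_regions,
    build_splicing_map,
    motif_enrichment,
    motif_positional_profile,
    position_enrichment,
    window_layout,
)
from qkisplice.simulate import GroundTruth, generate_clip_profiles, make_event_table


def peak_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "height", "strand",
                       "summit", "sequence", "kind"]
    )


class TestWindowLayout:
    def test_dimensions(self):
        lay = window_layout(flank=250, exon_bins=50)
        assert lay.total == 3 * 50 + 4 * 250
        assert lay.alt_3ss == 50 + 2 * 250
        assert lay.downstream_intron == (2 * 50 + 2 * 250, 2 * 50 + 4 * 250)


class TestBuildSplicingMap:
    def test_uniform_peaks_give_flat_profile(self):
        """A genome-wide constant-height peak yields a constant profile."""
        events = make_event_table(10)
        lo = int(events[["up_start", "dn_start"]].min().min()) - 1000
        hi = int(events[["up_end", "dn_end"]].max().max()) + 1000
        peaks = peak_frame(
            [("chr1", lo, hi, "blanket+", 2.0, "+", (lo + hi) // 2, "", "signal"),
             ("chr1", lo, hi, "blanket-", 2.0, "-", (lo + hi) // 2, "", "signal")]
        )
        profs = build_splicing_map(peaks, {"all": events})
        prof = profs["all"].mean_height
        assert np.allclose(prof, prof[0])

    def test_empty_group_rejected(self):
        events = make_event_table(2)
        with pytest.raises(SizeError):
            build_splicing_map(peak_frame([]), {"empty": events.iloc[:0]})

    def test_strand_mirror_consistency(self):
        """Mirroring the genome and flipping strands leaves the profile fixed."""
        events = make_event_table(2)
        plus = events[events.strand == "+"].copy()
        ev = plus.iloc[0]
        # one peak 30 nt into the upstream intron
        pk_start = int(ev.up_end) + 30
        peaks = peak_frame(
            [("chr1", pk_start, pk_start + 20, "p", 3.0, "+",
              pk_start + 10, "", "signal")]
        )
        prof_plus = build_splicing_map(peaks, {"g": plus})["g"].mean_height

        c = 10_000_000  # mirror coordinate
        def flip(a, b):
            return c - int(b), c - int(a)

        m = ev.copy()
        m["strand"] = "-"
        m["up_start"], m["up_end"] = flip(ev.up_start, ev.up_end)
        m["alt_start"], m["alt_end"] = flip(ev.alt_start, ev.alt_end)
        m["dn_start"], m["dn_end"] = flip(ev.dn_start, ev.dn_end)
        s, e = flip(pk_start, pk_start + 20)
        peaks_m = peak_frame(
            [("chr1", s, e, "p", 3.0, "-", s + 10, "", "signal")]
        )
        prof_minus = build_splicing_map(
            peaks_m, {"g": pd.DataFrame([m])}
        )["g"].mean_height
        assert np.allclose(prof_plus, prof_minus)


class TestPositionEnrichment:
    def _profiles_from_matrices(self, g, b):
        from qkisplice.clipmap import SplicingMapProfile

        lay = window_layout(flank=5, exon_bins=2)
        mk = lambda m, lbl: SplicingMapProfile(
            label=lbl, layout=lay, mean_height=m.mean(axis=0),
            event_matrix=m, n_events=m.shape[0],
        )
        return mk(g, "g"), mk(b, "background")

    def test_identical_groups_give_no_enrichment(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 26))
        g, b = self._profiles_from_matrices(m.copy(), m.copy())
        neg = position_enrichment(g, b)
        assert (neg <= 1.0).all()  # p >= 0.1 everywhere

    def test_saturated_position_strongly_enriched(self):
        """Group covered, background empty: -log10(p) > 3 at n=50 vs 500."""
        g_mat = np.zeros((50, 26))
        b_mat = np.zeros((500, 26))
        g_mat[:, 7] = 5.0
        g, b = self._profiles_from_matrices(g_mat, b_mat)
        neg = position_enrichment(g, b)
        assert neg[7] > 3.0
        # agrees with a direct scipy call at that position
        direct = mannwhitneyu(g_mat[:, 7], b_mat[:, 7],
                              alternative="greater", method="asymptotic").pvalue
        assert neg[7] == pytest.approx(-np.log10(direct), rel=1e-6)
        assert neg[0] == 0.0  # all-zero position -> p = 1

    def test_single_event_group_flagged(self):
        g_mat = np.ones((1, 26))
        b_mat = np.zeros((10, 26))
        g, b = self._profiles_from_matrices(g_mat, b_mat)
        position_enrichment(g, b)
        assert g.low_confidence


class TestMapRecovery:
    def test_directional_placement_recovered(self, clip_setup):
        """Planted binding sides produce maximal enrichment in their windows."""
        events, truth, peaks = clip_setup
        side = events.event_id.map(truth.true_binding_side)
        groups = {
            "skip": events[side == "upstream_intron"],
            "incl": events[side == "downstream_intron"],
            "background": events[side == "none"],
        }
        profs = build_splicing_map(peaks, groups)
        lay = profs["skip"].layout
        e_skip = position_enrichment(profs["skip"], profs["background"])
        e_incl = position_enrichment(profs["incl"], profs["background"])
        # regulator-skipped exons: within 100 nt upstream of the 3'ss
        m = int(np.argmax(e_skip))
        assert lay.alt_3ss - 100 <= m <= lay.alt_3ss + 10
        # regulator-included exons: inside the downstream intron
        lo, hi = lay.downstream_intron
        assert lo <= int(np.argmax(e_incl)) < hi


class TestMotifs:
    def test_full_vs_none_enrichment(self):
        stats = motif_enrichment(["AAACUAACGG"] * 50, ["AGGGGGGGUU"] * 50)
        assert stats.peak_hit_fraction == 1.0
        assert stats.background_hit_fraction == 0.0
        assert stats.enrichment_p < 1e-10

    def test_equal_fractions_not_enriched(self):
        seqs = ["ACUAACGG"] * 10 + ["GGGGGGGG"] * 40
        stats = motif_enrichment(seqs, list(seqs))
        assert stats.enrichment_p >= 0.5

    def test_matches_fisher_oracle(self):
        peaks = ["ACUAAC"] * 30 + ["GGGGGG"] * 20
        bg = ["ACUAAC"] * 10 + ["GGGGGG"] * 40
        stats = motif_enrichment(peaks, bg)
        _, p = fisher_exact([[30, 20], [10, 40]], alternative="greater")
        assert stats.enrichment_p == pytest.approx(p, rel=1e-12)

    def test_dna_alphabet_accepted(self):
        stats = motif_enrichment(["AACTAACG"], ["GGGGGGGG"], motif="ACUAAC")
        assert stats.peak_hit_fraction == 1.0

    def test_empty_sets_rejected(self):
        with pytest.raises(SizeError):
            motif_enrichment([], ["ACGU"])


class TestMotifPositionalProfile:
    def test_planted_summit_motifs_mode_at_zero(self, clip_setup):
        _, _, peaks = clip_setup
        sig = peaks[peaks["kind"] == "signal"]
        hist = motif_positional_profile(sig)
        vals, counts = np.unique(hist["sense"], return_counts=True)
        assert vals[np.argmax(counts)] == 0

    def test_random_sequence_sense_matches_antisense(self):
        """On random sequence the sense/antisense hit counts are comparable."""
        rng = np.random.default_rng(9)
        rows = []
        for i in range(400):
            seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 60)])
            rows.append(("chr1", 0, 60, f"p{i}", 1.0, "+", 30, seq, "bg"))
        hist = motif_positional_profile(peak_frame(rows))
        n_s, n_a = len(hist["sense"]), len(hist["antisense"])
        if n_s + n_a >= 10:
            assert chisquare([n_s, n_a]).pvalue > 0.01

    def test_peak_without_sequence_excluded_and_counted(self):
        rows = [("chr1", 0, 10, "p0", 1.0, "+", 5, "ACUAACGGGG", "s"),
                ("chr1", 0, 10, "p1", 1.0, "+", 5, None, "s")]
        hist = motif_positional_profile(peak_frame(rows))
        assert hist["n_no_sequence"] == 1


class TestRegionAnnotation:
    def _annotation(self):
        rows = [
            ("chr1", "gene", 0, 1000, "+", "G1", "", "protein_coding"),
            ("chr1", "CDS", 100, 200, "+", "G1", "G1.t1", "protein_coding"),
            ("chr1", "five_prime_utr", 50, 100, "+", "G1", "G1.t1", "protein_coding"),
            ("chr1", "three_prime_utr", 200, 260, "+", "G1", "G1.t1", "protein_coding"),
            ("chr1", "gene", 2000, 2500, "+", "NC1", "", "lincRNA"),
            ("chr1", "exon", 2000, 2500, "+", "NC1", "NC1.t1", "lincRNA"),
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "feature", "start", "end", "strand",
                           "gene_id", "transcript_id", "gene_biotype"],
        )

    def _peaks_at(self, positions):
        return peak_frame(
            [("chr1", p - 5, p + 5, f"p{i}", 1.0, "+", p, "", "s")
             for i, p in enumerate(positions)]
        )

    def test_all_intronic(self):
        props, _ = annotate_peak_regions(self._peaks_at([500, 600, 700]),
                                         self._annotation())
        assert props["intron"] == 1.0

    def test_precedence_cds_over_intron(self):
        """Summit in both a CDS (one transcript) and an intron: CDS wins."""
        ann = self._annotation()
        overlap = pd.DataFrame(
            [("chr1", "gene", 0, 1000, "+", "G2", "", "protein_coding")],
            columns=ann.columns,
        )
        props, assign = annotate_peak_regions(
            self._peaks_at([150]), pd.concat([ann, overlap])
        )
        assert assign.iloc[0] == "CDS"

    def test_category_assignment_and_sum_to_one(self):
        props, assign = annotate_peak_regions(
            self._peaks_at([75, 150, 230, 2200, 500, 5000]),
            self._annotation(),
        )
        assert assign.tolist() == ["5'UTR", "CDS", "3'UTR", "ncRNA",
                                   "intron", "intergenic"]
        assert props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_peaks_rejected(self):
        with pytest.raises(SizeError):
            annotate_peak_regions(peak_frame([]), self._annotation())


class TestGeneratorMapIntegration:
    def test_map_recovery_over_seeds(self):
        """Across 6 seeds, the max enrichment for upstream-planted events
        falls within [3'ss-100, 3'ss+10] every time."""
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            events = make_event_table(40)
            truth = GroundTruth()
            for i, ev in enumerate(events.event_id):
                truth.true_delta_psi[ev] = 0.0
                if i < 8:
                    truth.responsive_event_ids.add(ev)
                    truth.true_delta_psi[ev] = -0.4
                    truth.true_binding_side[ev] = "upstream_intron"
                else:
                    truth.true_binding_side[ev] = "none"
            peaks = generate_clip_profiles(events, truth, seed=1000 + seed)
            side = events.event_id.map(truth.true_binding_side)
            profs = build_splicing_map(peaks, {
                "skip": events[side == "upstream_intron"],
                "background": events[side == "none"],
            })
            lay = profs["skip"].layout
            neg = position_enrichment(profs["skip"], profs["background"])
            m = int(np.argmax(neg))
            hits += int(lay.alt_3ss - 100 <= m <= lay.alt_3ss + 10)
        assert hits >= n_seeds - 1
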