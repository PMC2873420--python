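"""Anchored DBD search: anchor counting, tiers, iteration, expansion."""

import pytest

from rfxsurvey.align import local_align, corrected_pid
from rfxsurvey.domain_search import (RFX, RFX_LIKE, DomainHit, QueryDomain,
                                     check_anchors, classify_candidate,
                                     count_rfx_per_species, find_domain_hits,
                                     iterative_survey, map_anchors,
                                     write_catalog_tsv)
from rfxsurvey.exceptions import ParameterError
from rfxsurvey.io_formats import ProteinRecord, RunConfig, TaxonGroupOrdering
from rfxsurvey.synthetic import ImplantSpec, evolve_domain, simulate_proteome


def _substitute_positions(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = "A" if out[p] != "A" else "G"
    return "".join(out)


class TestCheckAnchors:
    def test_self_alignment_conserves_all_nine(self, dbd_seeds, scheme):
        q = dbd_seeds[0]
        aln = local_align(q.sequence, q.sequence, scheme)
        assert check_anchors(aln, q) == 9

    def test_two_substituted_anchors_leave_seven(self, dbd_seeds, scheme):
        q = dbd_seeds[0]
        broken = _substitute_positions(q.sequence, sorted(q.anchors)[:2])
        aln = local_align(q.sequence, broken, scheme)
        assert check_anchors(aln, q) == 7

    def test_anchor_outside_aligned_interval_not_conserved(self, dbd_seeds, scheme):
        q = dbd_seeds[0]
        first_anchor = min(q.anchors)
        # target holds only the part of the query after the first anchor
        target = q.sequence[first_anchor + 1:]
        aln = local_align(q.sequence, target, scheme)
        assert aln.query_interval[0] >= first_anchor + 1
        assert check_anchors(aln, q) == 8

    def test_mapped_anchors_point_at_identical_residues(self, dbd_seeds, scheme):
        q = dbd_seeds[0]
        target = "M" * 37 + evolve_domain(q, 0.3, True, 5) + "K" * 50
        aln = local_align(q.sequence, target, scheme)
        ts = aln.target_interval[0]
        extracted = target[ts:aln.target_interval[1]]
        for rel in map_anchors(aln, q):
            assert extracted[rel] in {q.sequence[a] for a in q.anchors}


class TestClassifyCandidate:
    def _hit(self, pid, anchors, dbd_seeds, scheme):
        q = dbd_seeds[0]
        aln = local_align(q.sequence, q.sequence, scheme)
        from rfxsurvey.align import SignificanceEstimate

        return DomainHit(protein=ProteinRecord("p", "sp", q.sequence), query=q,
                         alignment=aln, pid=pid, anchors_conserved=anchors,
                         significance=SignificanceEstimate(0.005, 199),
                         extracted_domain=q.sequence)

    @pytest.mark.parametrize("pid,anchors,tier", [
        (45.0, 9, RFX),        # clears both the 40% threshold and all 9 anchors
        (40.0, 9, RFX),        # boundary inclusive
        (29.0, 5, RFX_LIKE),   # the ARID2 pattern: sub-threshold, 5/9 anchors
        (27.0, 5, RFX_LIKE),   # the Mbre_cRFX3 pattern
        (45.0, 8, RFX_LIKE),   # high PID but one anchor missing
        (24.9, 5, None),       # below the like-tier floor
        (29.0, 4, None),       # too few anchors for any tier
    ])
    def test_tier_rules(self, pid, anchors, tier, dbd_seeds, scheme, config):
        hit = self._hit(pid, anchors, dbd_seeds, scheme)
        assert classify_candidate(hit, config) == tier


class TestFindDomainHits:
    def test_perfect_implant_found_with_full_pid_and_anchors(self, dbd_seeds,
                                                             scheme, config):
        sp = simulate_proteome("s", 5, [ImplantSpec(dbd_seeds[0], 0.0, True)],
                               (200, 300), 21)
        hits = find_domain_hits(sp.records, dbd_seeds[:1], scheme, config, 3)
        implant_hits = [h for h in hits if h.protein.id == "s_implant1"]
        assert len(implant_hits) == 1
        h = implant_hits[0]
        assert h.pid == 100.0
        assert h.anchors_conserved == 9
        assert h.extracted_domain == dbd_seeds[0].sequence

    def test_half_diverged_implant_significant_but_below_threshold(
            self, dbd_seeds, scheme, config):
        sp = simulate_proteome("s", 0, [ImplantSpec(dbd_seeds[0], 0.5, True)],
                               (150, 250), 22)
        hits = find_domain_hits(sp.records, dbd_seeds[:1], scheme, config, 4)
        assert len(hits) == 1
        # closed-form expectation: 100 * (1 - 0.5 * 67/76) ~ 56
        assert hits[0].significance.p_value <= config.significance_alpha
        assert 40 < hits[0].pid < 72

    def test_empty_proteome_gives_empty_result(self, dbd_seeds, scheme, config):
        assert find_domain_hits([], dbd_seeds, scheme, config, 0) == []

    def test_no_queries_rejected(self, scheme, config):
        with pytest.raises(ParameterError):
            find_domain_hits([ProteinRecord("p", "s", "MKV")], [], scheme, config, 0)


def _proteomes_for_survey(dbd_seeds, divergences, rng_base=100):
    """One species per divergence, one implant each plus 5 decoys."""
    out = {}
    for k, d in enumerate(divergences):
        name = f"sp{k}"
        sp = simulate_proteome(name, 5, [ImplantSpec(dbd_seeds[0], d, True)],
                               (150, 250), rng_base + k)
        out[name] = sp.records
    return out


class TestIterativeSurvey:
    def test_single_group_reduces_to_find_plus_classify(self, dbd_seeds, scheme,
                                                        config):
        proteomes = _proteomes_for_survey(dbd_seeds, [0.1, 0.2])
        ordering = TaxonGroupOrdering((("only", ("sp0", "sp1")),))
        catalog = iterative_survey(proteomes, ordering, dbd_seeds[:2], scheme,
                                   config, 17)
        from rfxsurvey.domain_search import derive_seed

        for sp in ("sp0", "sp1"):
            hits = find_domain_hits(proteomes[sp], dbd_seeds[:2], scheme, config,
                                    derive_seed(17, sp))
            expect = {(h.protein.id, classify_candidate(h, config))
                      for h in hits if classify_candidate(h, config)}
            got = {(c.hit.protein.id, c.tier) for c in catalog.calls_for(sp)}
            assert got == expect

    def test_expansion_rescues_a_two_step_homolog_chain(self, dbd_seeds, scheme,
                                                        config):
        seed = dbd_seeds[0]
        step1 = evolve_domain(seed, 0.5, True, 41)
        q1 = QueryDomain("step1", step1, seed.anchors)
        step2 = evolve_domain(q1, 0.5, True, 42)
        # construction premise: the chained domain is near step1 (~53% PID)
        # but past the acceptance threshold from the seed (~34% expected)
        assert corrected_pid(local_align(seed.sequence, step2, scheme), 76) < 40
        assert corrected_pid(local_align(seed.sequence, step1, scheme), 76) >= 40
        assert corrected_pid(local_align(step1, step2, scheme), 76) >= 40
        near = simulate_proteome("near", 5, [ImplantSpec(q1, 0.0, True)],
                                 (150, 250), 43)
        q2 = QueryDomain("step2", step2, seed.anchors)
        far = simulate_proteome("far", 5, [ImplantSpec(q2, 0.0, True)],
                                (150, 250), 44)
        proteomes = {"near": near.records, "far": far.records}
        ordering = TaxonGroupOrdering((("g1", ("near",)), ("g2", ("far",))))

        def rfx_proteins(expansion):
            cat = iterative_survey(proteomes, ordering, dbd_seeds[:1], scheme,
                                   config, 19, expansion=expansion)
            return {(sp, c.hit.protein.id) for sp in cat.species
                    for c in cat.calls_for(sp) if c.tier == RFX}

        with_exp = rfx_proteins(True)
        without = rfx_proteins(False)
        assert ("far", "far_implant1") in with_exp
        assert ("far", "far_implant1") not in without
        assert without <= with_exp  # expansion dominance

    def test_rerun_same_seed_is_byte_identical(self, dbd_seeds, scheme, config,
                                               tmp_path):
        proteomes = _proteomes_for_survey(dbd_seeds, [0.15, 0.3])
        ordering = TaxonGroupOrdering((("g1", ("sp0",)), ("g2", ("sp1",))))
        paths = []
        for run in (1, 2):
            cat = iterative_survey(proteomes, ordering, dbd_seeds[:1], scheme,
                                   config, 23)
            p = tmp_path / f"cat{run}.tsv"
            write_catalog_tsv(cat, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_unlisted_species_rejected_by_name(self, dbd_seeds, scheme, config):
        proteomes = _proteomes_for_survey(dbd_seeds, [0.1])
        ordering = TaxonGroupOrdering((("g", ("other",)),))
        with pytest.raises(ParameterError, match="sp0"):
            iterative_survey(proteomes, ordering, dbd_seeds[:1], scheme, config, 0)

    def test_names_assigned_by_descending_pid(self, dbd_seeds, scheme, config):
        seed = dbd_seeds[0]
        sp = simulate_proteome(
            "s", 3,
            [ImplantSpec(seed, 0.25, True), ImplantSpec(seed, 0.05, True)],
            (150, 250), 31)
        ordering = TaxonGroupOrdering((("g", ("s",)),))
        cat = iterative_survey({"s": sp.records}, ordering, dbd_seeds[:1],
                               scheme, config, 7)
        calls = cat.calls_for("s")
        assert [c.assigned_name for c in calls] == [f"cRFX{i+1}"
                                                    for i in range(len(calls))]
        pids = [c.hit.pid for c in calls]
        assert pids == sorted(pids, reverse=True)


class TestCountRfx:
    def test_like_tier_excluded_from_counts(self, dbd_seeds, scheme, config):
        # one strong implant (RFX) + one weak implant (RFX-like territory)
        seed = dbd_seeds[0]
        weak = evolve_domain(seed, 0.55, False, 61)  # anchors broken partially
        sp = simulate_proteome("s", 3, [ImplantSpec(seed, 0.1, True)],
                               (150, 250), 62)
        ordering = TaxonGroupOrdering((("g", ("s",)),))
        cat = iterative_survey({"s": sp.records}, ordering, dbd_seeds[:1],
                               scheme, config, 8)
        counts = count_rfx_per_species(cat)
        assert counts["s"] == sum(
            1 for c in cat.calls_for("s") if c.tier == RFX)

    def test_empty_species_counts_zero(self):
        from rfxsurvey.domain_search import RFXCatalog

        cat = RFXCatalog(species=("empty",), calls={})
        assert count_rfx_per_species(cat) == {"empty": 0}
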