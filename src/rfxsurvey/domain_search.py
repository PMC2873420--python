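"""Anchored-domain homology search with tiered RFX / RFX-like classification.

The survey's core procedure: every proteome is scanned with a list of query
domains (76-aa RFX DNA-binding domains, DBDs); a candidate is accepted into
the RFX tier only if its corrected percent identity reaches the acceptance
threshold (default 40%) *and* all nine DNA-contact anchor residues are
conserved.  Weaker candidates that keep at least five anchors above a PID
floor form the RFX-like tier (the ARID2 pattern) and are reported but never
counted as RFX genes.

Taxon groups are processed in a fixed order; after each group the DBDs of
newly accepted RFX-tier hits are appended to the query list (query
expansion), which is what lets the search walk out to divergent lineages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

from .align import (LocalAlignment, SubstitutionScheme, corrected_pid,
                    empirical_significance, local_align, local_score,
                    SignificanceEstimate)
from .exceptions import InputError, ParameterError
from .io_formats import ProteinRecord, RunConfig, TaxonGroupOrdering, log

RFX = "RFX"
RFX_LIKE = "RFX_LIKE"


def derive_seed(base: int, *keys) -> int:
    """Stable per-item child seed below 2**31, mixed from strings/ints via CRC."""
    h = zlib.crc32(repr((base,) + keys).encode())
    return (base * 2654435761 + h) % (2**31 - 1)


@dataclass(frozen=True)
class QueryDomain:
    """A seed peptide with the 0-based positions of its DNA-contact anchors."""

    name: str
    sequence: str
    anchors: frozenset
    provenance: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"query {self.name!r} has an empty sequence")
        if any(not (0 <= a < len(self.sequence)) for a in self.anchors):
            raise ParameterError(
                f"query {self.name!r}: anchor outside [0, {len(self.sequence)})")
        object.__setattr__(self, "anchors", frozenset(int(a) for a in self.anchors))


@dataclass(frozen=True)
class DomainHit:
    """Best accepted local alignment of one query against one protein."""

    protein: ProteinRecord
    query: QueryDomain
    alignment: LocalAlignment
    pid: float
    anchors_conserved: int
    significance: SignificanceEstimate
    extracted_domain: str


@dataclass(frozen=True)
class RFXCall:
    hit: DomainHit
    tier: str
    assigned_name: str = ""


@dataclass(frozen=True)
class RFXCatalog:
    """Per-species classified calls; ``species`` lists every surveyed species."""

    species: tuple
    calls: dict  # species -> tuple[RFXCall]

    def calls_for(self, species: str):
        return self.calls.get(species, ())


def check_anchors(aln: LocalAlignment, query: QueryDomain) -> int:
    """Count query anchors conserved in an alignment.

    An anchor counts only if it lies inside the aligned query interval, is
    aligned to a residue (not a gap), and that residue is identical.
    """
    qs = aln.query_interval[0]
    conserved = 0
    qpos = qs
    for qc, tc in zip(aln.aligned_query, aln.aligned_target):
        if qc != "-":
            if qpos in query.anchors and tc != "-" and qc == tc and qc != "X":
                conserved += 1
            qpos += 1
    return conserved


def map_anchors(aln: LocalAlignment, query: QueryDomain) -> frozenset:
    """Anchor positions mapped onto the extracted target-side domain.

    Returned positions are relative to the start of the degapped target
    region; anchors lost to gaps or outside the aligned interval are dropped.
    """
    qpos = aln.query_interval[0]
    tpos = 0  # relative to target interval start
    mapped = set()
    for qc, tc in zip(aln.aligned_query, aln.aligned_target):
        if qc != "-" and tc != "-" and qpos in query.anchors:
            mapped.add(tpos)
        if qc != "-":
            qpos += 1
        if tc != "-":
            tpos += 1
    return frozenset(mapped)


def best_hit_for_protein(protein: ProteinRecord, queries, scheme: SubstitutionScheme,
                         config: RunConfig, rng_seed: int) -> DomainHit | None:
    """Best query hit on one protein, or None if not significant.

    Queries are ranked by local score (cheap, score-only pass); ties are
    resolved by corrected PID, then query list order.  Significance of the
    winning pair is assessed by the composition-preserving shuffle null.
    """
    scores = [local_score(q.sequence, protein.sequence, scheme) for q in queries]
    best_score = max(scores)
    if best_score <= 0:
        return None
    best = None
    for q, s in zip(queries, scores):
        if s != best_score:
            continue
        aln = local_align(q.sequence, protein.sequence, scheme)
        pid = corrected_pid(aln, len(q.sequence))
        if best is None or pid > best[1]:
            best = (q, pid, aln)
    q, pid, aln = best
    sig = empirical_significance(aln.score, q.sequence, protein.sequence, scheme,
                                 n_shuffles=config.n_shuffles,
                                 rng_seed=derive_seed(rng_seed, protein.id, q.name))
    if sig.p_value > config.significance_alpha:
        return None
    ts, te = aln.target_interval
    return DomainHit(protein=protein, query=q, alignment=aln, pid=pid,
                     anchors_conserved=check_anchors(aln, q), significance=sig,
                     extracted_domain=protein.sequence[ts:te])


def find_domain_hits(proteome, queries, scheme: SubstitutionScheme,
                     config: RunConfig, rng_seed: int) -> list[DomainHit]:
    """Scan a proteome with every query; keep per protein the best significant hit.

    Output is sorted by (species, protein id, descending PID).
    """
    if not queries:
        raise ParameterError("at least one query is required")
    hits = []
    for protein in proteome:
        hit = best_hit_for_protein(protein, queries, scheme, config, rng_seed)
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (h.protein.species, h.protein.id, -h.pid))
    return hits


def classify_candidate(hit: DomainHit, config: RunConfig) -> str | None:
    """Tier a significant hit: RFX, RFX_LIKE, or None.

    RFX requires PID >= the acceptance threshold and *all* required anchors;
    RFX_LIKE requires PID >= the like-tier floor and at least the reduced
    anchor count.
    """
    if hit.pid >= config.pid_accept_threshold and \
            hit.anchors_conserved >= config.anchors_required_full:
        return RFX
    if hit.pid >= config.pid_rfxlike_floor and \
            hit.anchors_conserved >= config.anchors_required_like:
        return RFX_LIKE
    return None


def _assign_names(calls):
    """Name calls cRFX1, cRFX2, ... within a species by descending PID."""
    ordered = sorted(calls, key=lambda c: (-c.hit.pid, c.hit.protein.id))
    return tuple(RFXCall(hit=c.hit, tier=c.tier, assigned_name=f"cRFX{i + 1}")
                 for i, c in enumerate(ordered))


def iterative_survey(proteomes: dict, ordering: TaxonGroupOrdering, seeds,
                     scheme: SubstitutionScheme, config: RunConfig,
                     rng_seed: int, expansion: bool = True) -> RFXCatalog:
    """Run the survey over taxon groups in order with query expansion.

    Within a group every species is searched with the query list frozen at
    group start; after the group, the extracted DBD of each newly accepted
    RFX-tier hit (anchors mapped through its alignment) joins the query list,
    deduplicated by exact sequence.  With ``expansion=False`` the seed list
    is used throughout.
    """
    covered = set(ordering.species)
    missing = sorted(set(proteomes) - covered)
    if missing:
        raise ParameterError(f"species missing from taxon ordering: {missing}")
    queries = list(seeds)
    known = {q.sequence for q in queries}
    calls: dict[str, tuple] = {}
    species_list = [sp for sp in ordering.species if sp in proteomes]
    for group_name, members in ordering.groups:
        frozen = list(queries)
        new_domains = []
        for sp in members:
            if sp not in proteomes:
                continue
            hits = find_domain_hits(proteomes[sp], frozen, scheme, config,
                                    derive_seed(rng_seed, sp))
            sp_calls = []
            for hit in hits:
                tier = classify_candidate(hit, config)
                if tier is None:
                    continue
                sp_calls.append(RFXCall(hit=hit, tier=tier))
                if tier == RFX:
                    anchors = map_anchors(hit.alignment, hit.query)
                    new_domains.append(QueryDomain(
                        name=f"{sp}:{hit.protein.id}", sequence=hit.extracted_domain,
                        anchors=anchors, provenance=f"expanded from {hit.query.name}"))
            calls[sp] = _assign_names(sp_calls)
        if expansion:
            for dom in new_domains:
                if dom.sequence not in known:
                    known.add(dom.sequence)
                    queries.append(dom)
            log.info("group %s done; query list now %d domains",
                     group_name, len(queries))
    return RFXCatalog(species=tuple(species_list), calls=calls)


def count_rfx_per_species(catalog: RFXCatalog) -> dict:
    """Distinct proteins with RFX-tier calls per species (RFX-like excluded)."""
    counts = {}
    for sp in catalog.species:
        proteins = {c.hit.protein.id for c in catalog.calls_for(sp) if c.tier == RFX}
        counts[sp] = len(proteins)
    return counts


def write_catalog_tsv(catalog: RFXCatalog, path) -> None:
    """Catalog TSV: one row per call with PID, anchors, p-value and DBD sequence."""
    cols = ["species", "protein_id", "assigned_name", "tier", "pid",
            "anchors_conserved", "p_value", "domain_start", "domain_end",
            "dbd_sequence"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for sp in catalog.species:
            for c in catalog.calls_for(sp):
                ts, te = c.hit.alignment.target_interval
                fh.write("\t".join([
                    sp, c.hit.protein.id, c.assigned_name, c.tier,
                    f"{c.hit.pid:.2f}", str(c.hit.anchors_conserved),
                    f"{c.hit.significance.p_value:.6g}", str(ts), str(te),
                    c.hit.extracted_domain,
                ]) + "\n")
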