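"""End-to-end orchestration: survey, scan, tree, architectures, report."""

from __future__ import annotations

from .align import SubstitutionScheme, default_scheme
from .domain_search import RFX, derive_seed, iterative_survey
from .ift_scan import IFTQuerySet, build_matrix
from .io_formats import RunConfig, TaxonGroupOrdering
from .phylogeny import assign_clades, distance_matrix, nj_tree
from .profiles import architecture
from .report import ReportBundle, build_report


def run_survey(proteomes: dict, ordering: TaxonGroupOrdering, seeds,
               ift_queries: IFTQuerySet, config: RunConfig | None = None,
               scheme: SubstitutionScheme | None = None, profiles=None,
               clade_references: dict | None = None,
               ciliation_overrides: dict | None = None,
               expansion: bool = True):
    """Run the whole survey and return ``(bundle, catalog, matrix, tree)``.

    ``clade_references`` maps reference DBD sequences to groups as
    ``{label: (sequence, group)}``; when given (and at least one DBD is
    recovered) an NJ tree over reference plus recovered DBDs is inferred and
    query leaves are clade-assigned.  ``profiles`` is an iterable of
    *calibrated* DomainProfiles used for architecture strings.
    """
    config = config or RunConfig()
    scheme = scheme or default_scheme()
    catalog = iterative_survey(proteomes, ordering, seeds, scheme, config,
                               config.random_seed, expansion=expansion)
    matrix = build_matrix(proteomes, ift_queries, scheme, config,
                          derive_seed(config.random_seed, "matrix"),
                          species_order=catalog.species)
    tree = None
    clades: dict = {}
    if clade_references:
        sequences = {lab: seq for lab, (seq, _g) in clade_references.items()}
        refmap = {lab: g for lab, (_s, g) in clade_references.items()}
        for sp in catalog.species:
            for call in catalog.calls_for(sp):
                if call.tier == RFX:
                    sequences[f"{sp}:{call.hit.protein.id}"] = call.hit.extracted_domain
        if len(sequences) >= 3 and len(sequences) > len(refmap):
            tree = nj_tree(distance_matrix(sequences, scheme))
            clades = assign_clades(tree, refmap)
    architectures: dict = {}
    if profiles is not None:
        for sp in catalog.species:
            by_protein = {}
            for call in catalog.calls_for(sp):
                by_protein[call.hit.protein.id] = architecture(
                    call.hit.protein, profiles, dbd_call=call.hit)
            architectures[sp] = by_protein
    bundle: ReportBundle = build_report(catalog, matrix, clades=clades,
                                        architectures=architectures,
                                        ciliation_overrides=ciliation_overrides)
    return bundle, catalog, matrix, tree
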