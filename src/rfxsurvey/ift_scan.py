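"""Conservation scanning of the 24 ciliary IFT/BBS queries per species.

The ciliary machinery is organised as four modules — Motors, Complex A,
Complex B and the BBS complex, 24 query proteins in total.  Each species'
proteome is scanned with every query; a cell of the conservation matrix is
the corrected PID of the best significant hit, or absent.  A computed
ciliation surrogate (enough queries conserved above a PID floor) feeds the
co-occurrence classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import SubstitutionScheme, corrected_pid, empirical_significance, \
    local_align, local_score
from .domain_search import QueryDomain, derive_seed
from .exceptions import ParameterError
from .io_formats import RunConfig

#: Canonical module composition of the IFT machinery (24 human query genes).
IFT_MODULES = (
    ("Motors", ("DYNC2H1", "KIFAP3", "KIF17", "KIF3B", "KIF3A")),
    ("ComplexA", ("IFT122", "IFT140", "WDR35", "WDR19")),
    ("ComplexB", ("IFT88", "IFT80", "IFT172", "IFT57", "CLUAP1", "IFT52",
                  "IFT20", "IFT81", "IFT74")),
    ("BBS", ("BBS5", "TTC8", "BBS2", "ARL6", "BBS1", "BBS7")),
)


@dataclass(frozen=True)
class IFTQuerySet:
    """Ordered (module name, [full-protein queries]) pairs; 24 queries total."""

    modules: tuple  # ((name, (QueryDomain, ...)), ...)

    def __post_init__(self):
        for _name, queries in self.modules:
            for q in queries:
                if q.anchors:
                    raise ParameterError(
                        f"IFT query {q.name!r} must not carry anchors")

    @property
    def queries(self) -> tuple:
        return tuple(q for _m, qs in self.modules for q in qs)

    @property
    def gene_names(self) -> tuple:
        return tuple(q.name for q in self.queries)


def query_set_from_records(records, modules=IFT_MODULES) -> IFTQuerySet:
    """Group query records (ids = gene names) into the canonical modules."""
    by_id = {r.id: r for r in records}
    out = []
    for mod_name, genes in modules:
        qs = []
        for g in genes:
            if g not in by_id:
                raise ParameterError(f"query {g!r} missing for module {mod_name!r}")
            qs.append(QueryDomain(name=g, sequence=by_id[g].sequence,
                                  anchors=frozenset()))
        out.append((mod_name, tuple(qs)))
    return IFTQuerySet(modules=tuple(out))


@dataclass(frozen=True)
class ConservationMatrix:
    """Species x gene grid of best corrected PIDs (None = no accepted hit)."""

    species: tuple
    genes: tuple
    cells: dict  # species -> {gene: float | None}
    modules: tuple
    ciliated: dict = field(default_factory=dict)  # species -> bool

    def row(self, species: str) -> dict:
        return self.cells[species]


def scan_species(proteome, queries: IFTQuerySet, scheme: SubstitutionScheme,
                 config: RunConfig, rng_seed: int) -> dict:
    """One matrix row: best-hit corrected PID per IFT query, None if absent.

    For each query the best-scoring protein in the proteome is located with a
    score-only pass; the cell is filled only if the shuffle-null p-value of
    that best pair reaches ``config.significance_alpha``.
    """
    row: dict[str, float | None] = {}
    for q in queries.queries:
        best_protein, best_score = None, 0
        for protein in proteome:
            s = local_score(q.sequence, protein.sequence, scheme)
            if s > best_score:
                best_protein, best_score = protein, s
        if best_protein is None:
            row[q.name] = None
            continue
        sig = empirical_significance(
            best_score, q.sequence, best_protein.sequence, scheme,
            n_shuffles=config.n_shuffles,
            rng_seed=derive_seed(rng_seed, q.name, best_protein.id))
        if sig.p_value > config.significance_alpha:
            row[q.name] = None
            continue
        aln = local_align(q.sequence, best_protein.sequence, scheme)
        row[q.name] = corrected_pid(aln, len(q.sequence))
    return row


def call_ciliated(row: dict, config: RunConfig) -> bool:
    """Computed ciliation surrogate: enough queries conserved above the floor.

    True iff the fraction of queries with a present cell at PID >=
    ``cilia_call_min_pid`` reaches ``cilia_call_fraction`` (boundary
    inclusive).
    """
    present = sum(1 for v in row.values()
                  if v is not None and v >= config.cilia_call_min_pid)
    return present >= config.cilia_call_fraction * len(row)


def module_completeness(row: dict, queries: IFTQuerySet) -> dict:
    """Fraction of genes with a present cell, per IFT module."""
    out = {}
    for mod_name, qs in queries.modules:
        present = sum(1 for q in qs if row[q.name] is not None)
        out[mod_name] = present / len(qs)
    return out


def build_matrix(proteomes: dict, queries: IFTQuerySet, scheme, config,
                 rng_seed: int, species_order=None) -> ConservationMatrix:
    """Scan every species and assemble the full conservation matrix."""
    order = tuple(species_order) if species_order is not None else tuple(proteomes)
    cells = {}
    ciliated = {}
    for sp in order:
        row = scan_species(proteomes[sp], queries, scheme, config,
                           derive_seed(rng_seed, "ift", sp))
        cells[sp] = row
        ciliated[sp] = call_ciliated(row, config)
    return ConservationMatrix(species=order, genes=queries.gene_names,
                              cells=cells, modules=queries.modules,
                              ciliated=ciliated)
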