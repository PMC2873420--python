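"""Per-species cilia/RFX co-occurrence states and the integrated survey report.

Every species falls into exactly one of four evolutionary states depending
on whether it retains RFX transcription factors and/or a conserved ciliary
(IFT) complement: BOTH, CILIA_ONLY (the green-alga pattern), RFX_ONLY (the
yeast pattern), or NEITHER.  The report bundles the RFX catalog, the IFT
conservation matrix, clade labels and domain architectures into one table
plus the four-state summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domain_search import RFXCatalog, count_rfx_per_species
from .exceptions import ParameterError
from .ift_scan import ConservationMatrix
from .io_formats import log

BOTH = "BOTH"
CILIA_ONLY = "CILIA_ONLY"
RFX_ONLY = "RFX_ONLY"
NEITHER = "NEITHER"
STATES = (BOTH, CILIA_ONLY, RFX_ONLY, NEITHER)


@dataclass(frozen=True)
class SpeciesState:
    species: str
    rfx_count: int
    ciliated: bool
    state: str


def species_state(rfx_count: int, ciliated: bool) -> str:
    """The four-way partition: has RFX? has cilia?"""
    if rfx_count < 0:
        raise ParameterError(f"rfx_count must be non-negative, got {rfx_count}")
    if rfx_count >= 1:
        return BOTH if ciliated else RFX_ONLY
    return CILIA_ONLY if ciliated else NEITHER


@dataclass(frozen=True)
class ReportBundle:
    """Integrated per-species rows plus the four-state summary counts."""

    species: tuple
    states: dict          # species -> SpeciesState
    matrix: ConservationMatrix
    catalog: RFXCatalog
    clades: dict = field(default_factory=dict)        # leaf label -> group
    architectures: dict = field(default_factory=dict)  # species -> {protein: str}

    def summary_counts(self) -> dict:
        counts = {s: 0 for s in STATES}
        for st in self.states.values():
            counts[st.state] += 1
        return counts

    def to_tsv(self, path) -> None:
        genes = self.matrix.genes
        cols = ["species", "rfx_count", "ciliated", "state", "clades",
                "architectures"] + list(genes)
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for sp in self.species:
                st = self.states[sp]
                clade_labels = ",".join(
                    f"{c.assigned_name}:{self.clades[f'{sp}:{c.hit.protein.id}']}"
                    for c in self.catalog.calls_for(sp)
                    if f"{sp}:{c.hit.protein.id}" in self.clades)
                archs = ",".join(
                    f"{pid}:{a}" for pid, a in
                    sorted(self.architectures.get(sp, {}).items()))
                row = [sp, str(st.rfx_count), str(int(st.ciliated)), st.state,
                       clade_labels, archs]
                for g in genes:
                    v = self.matrix.cells[sp][g]
                    row.append("" if v is None else f"{v:.1f}")
                fh.write("\t".join(row) + "\n")

    def summary_tsv(self, path) -> None:
        counts = self.summary_counts()
        with open(path, "w") as fh:
            fh.write("state\tcount\n")
            for s in STATES:
                fh.write(f"{s}\t{counts[s]}\n")


def build_report(catalog: RFXCatalog, matrix: ConservationMatrix,
                 clades: dict | None = None, architectures: dict | None = None,
                 ciliation_overrides: dict | None = None) -> ReportBundle:
    """Assemble the integrated report from one run's outputs.

    ``ciliation_overrides`` maps species to a literature-based ciliated flag
    that replaces the computed surrogate (overrides are logged).  The catalog
    and matrix must cover the same species set.
    """
    cat_sp = set(catalog.species)
    mat_sp = set(matrix.species)
    if cat_sp != mat_sp:
        only_cat = sorted(cat_sp - mat_sp)
        only_mat = sorted(mat_sp - cat_sp)
        raise ParameterError(
            f"species mismatch between catalog and matrix: catalog-only "
            f"{only_cat}, matrix-only {only_mat}")
    counts = count_rfx_per_species(catalog)
    overrides = ciliation_overrides or {}
    states = {}
    for sp in matrix.species:
        ciliated = matrix.ciliated.get(sp, False)
        if sp in overrides:
            log.info("ciliation override for %s: %s -> %s", sp, ciliated,
                     overrides[sp])
            ciliated = bool(overrides[sp])
        states[sp] = SpeciesState(species=sp, rfx_count=counts[sp],
                                  ciliated=ciliated,
                                  state=species_state(counts[sp], ciliated))
    return ReportBundle(species=matrix.species, states=states, matrix=matrix,
                        catalog=catalog, clades=clades or {},
                        architectures=architectures or {})
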