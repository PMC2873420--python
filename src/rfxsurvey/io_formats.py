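"""Readers and writers for the pipeline's external formats, plus run configuration.

Formats touched: peptide multi-FASTA (proteomes, query sets), a species
manifest (TSV mapping FASTA file -> species -> taxon group), flat YAML run
configuration, and TSV conservation matrices.  All coordinates written
anywhere by this package are 0-based, half-open.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigError, ParseError

log = logging.getLogger("rfxsurvey")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with level prefixes."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


@dataclass(frozen=True)
class ProteinRecord:
    """One peptide: stable id, species label, uppercase sequence over 20 aa + 'X'."""

    id: str
    species: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class TaxonGroupOrdering:
    """Ordered taxon groups driving the iterative survey.

    ``groups`` is an ordered list of ``(group name, [species labels])``; every
    species appears in exactly one group.
    """

    groups: tuple

    def __post_init__(self):
        if not self.groups:
            raise ConfigError("at least one taxon group is required")
        seen = {}
        for name, species in self.groups:
            for sp in species:
                if sp in seen:
                    raise ConfigError(
                        f"species {sp!r} appears in groups {seen[sp]!r} and {name!r}")
                seen[sp] = name
        object.__setattr__(self, "groups", tuple(
            (name, tuple(species)) for name, species in self.groups))

    @property
    def species(self) -> tuple:
        return tuple(sp for _, members in self.groups for sp in members)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and knobs of one survey run.

    pid_accept_threshold  -- corrected-PID acceptance for the RFX tier (%, default 40)
    pid_rfxlike_floor     -- corrected-PID floor for the RFX-like tier (%, default 25)
    anchors_required_full -- DNA-contact anchors required for the RFX tier (default 9)
    anchors_required_like -- anchors required for the RFX-like tier (default 5)
    significance_alpha    -- shuffle-null acceptance p-value (default 0.01)
    cilia_call_fraction   -- fraction of IFT queries needed to call a species ciliated
    cilia_call_min_pid    -- PID at which an IFT query counts toward that fraction
    random_seed           -- master seed for every stochastic step
    """

    pid_accept_threshold: float = 40.0
    pid_rfxlike_floor: float = 25.0
    anchors_required_full: int = 9
    anchors_required_like: int = 5
    significance_alpha: float = 0.01
    cilia_call_fraction: float = 0.5
    cilia_call_min_pid: float = 20.0
    random_seed: int = 0
    n_shuffles: int = 199

    def __post_init__(self):
        if not (0 <= self.pid_rfxlike_floor < self.pid_accept_threshold <= 100):
            raise ConfigError(
                "require 0 <= pid_rfxlike_floor < pid_accept_threshold <= 100 "
                f"(got {self.pid_rfxlike_floor}, {self.pid_accept_threshold})")
        if not (0 < self.significance_alpha < 1):
            raise ConfigError(f"significance_alpha must be in (0, 1), got "
                              f"{self.significance_alpha}")
        if self.anchors_required_like > self.anchors_required_full:
            raise ConfigError("anchors_required_like exceeds anchors_required_full")
        if self.n_shuffles < 99:
            raise ConfigError("n_shuffles must be at least 99")


def load_config(path) -> RunConfig:
    """Load a flat YAML config; unspecified keys take RunConfig defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} is not a flat key/value mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def read_fasta(path, species: str = "") -> list[ProteinRecord]:
    """Read a peptide multi-FASTA into ProteinRecords.

    The header token before the first whitespace becomes the id (the rest is
    kept as description but ignored downstream); sequences are uppercased and
    trailing '*' stop symbols stripped.  Duplicate ids and sequence lines
    before any header are parse errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    cur_id = None
    cur_desc = ""
    chunks: list[str] = []

    def flush():
        if cur_id is None:
            return
        seq = "".join(chunks).upper().rstrip("*")
        if not seq:
            raise ParseError(f"record {cur_id!r} has an empty sequence")
        records.append(ProteinRecord(cur_id, species, seq, cur_desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen:
                    raise ParseError(f"{path}:{lineno}: duplicate id {cur_id!r}")
                seen.add(cur_id)
                chunks = []
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence line before any FASTA header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records, path) -> None:
    """Write records as multi-FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def read_manifest(path):
    """Read a proteome manifest TSV: columns path, species, group.

    Paths are resolved relative to the manifest's directory.  Returns
    ``(ordering, {species: fasta path})`` where the group ordering follows
    first appearance in the file.
    """
    base = Path(path).parent
    group_order: list[str] = []
    members: dict[str, list[str]] = {}
    fasta_by_species: dict[str, Path] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated "
                                 f"columns (path, species, group)")
            rel, species, group = (p.strip() for p in parts)
            if species in fasta_by_species:
                raise ParseError(f"{path}:{lineno}: duplicate species {species!r}")
            fasta_by_species[species] = base / rel
            if group not in members:
                group_order.append(group)
                members[group] = []
            members[group].append(species)
    ordering = TaxonGroupOrdering(tuple((g, tuple(members[g])) for g in group_order))
    return ordering, fasta_by_species


# --- conservation matrix TSV -------------------------------------------------

ABSENT = None  # cell value for "no accepted hit"


def write_matrix_tsv(matrix, path) -> None:
    """Write a species x gene conservation matrix as TSV.

    First row: 'species' then gene names in module-grouped order; one row per
    species in input order; absent cells are written empty.
    """
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(matrix.genes) + "\n")
        for sp in matrix.species:
            cells = []
            for g in matrix.genes:
                v = matrix.cells[sp][g]
                cells.append("" if v is None else f"{v:.1f}")
            fh.write(sp + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path):
    """Round-trip reader for :func:`write_matrix_tsv` output."""
    from .ift_scan import ConservationMatrix  # local import: avoid cycle

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "species":
            raise ParseError(f"{path}: first column must be 'species'")
        genes = tuple(header[1:])
        species: list[str] = []
        cells: dict[str, dict[str, float | None]] = {}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(genes) + 1:
                raise ParseError(f"{path}:{lineno}: wrong column count")
            sp = parts[0]
            species.append(sp)
            cells[sp] = {g: (None if v == "" else float(v))
                         for g, v in zip(genes, parts[1:])}
    return ConservationMatrix(species=tuple(species), genes=genes, cells=cells,
                              modules=(("all", genes),))
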