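"""Loaders for the packaged seed fixtures.

The shipped seed files are *synthetic* stand-ins generated by
``scripts/build_seed_fixtures.py``: a family of 76-aa DBD seed queries
sharing nine invariant anchor positions, 24 IFT/BBS query stand-ins
(200-400 aa), and aligned instance sets for the AD/B/C/D/DD profiles.  They
reproduce the *structure* of the real query sets (lengths, anchor geometry,
module grouping, within-family similarity), not real database sequences;
every loader accepts a path so curated real data can be dropped in.
"""

from __future__ import annotations

from importlib.resources import files

from .domain_search import QueryDomain
from .exceptions import ParseError
from .ift_scan import IFTQuerySet, query_set_from_records
from .io_formats import read_fasta

#: Nine 0-based DNA-contact anchor positions shared by all packaged DBD seeds.
DBD_ANCHORS = frozenset({13, 18, 21, 33, 37, 44, 51, 62, 69})
DBD_LENGTH = 76


def _data_path(name: str) -> str:
    return str(files("rfxsurvey.data").joinpath(name))


def load_dbd_seeds(fasta_path=None, anchors_path=None) -> list:
    """The packaged DBD seed query set with per-seed anchor positions."""
    fasta_path = fasta_path or _data_path("rfx_dbd_seeds_synthetic.fasta")
    anchors_path = anchors_path or _data_path("dbd_anchors_synthetic.tsv")
    anchors = {}
    with open(anchors_path) as fh:
        anchor_lines = fh.read().splitlines()
    for lineno, line in enumerate(anchor_lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{anchors_path}:{lineno}: expected name<TAB>positions")
        anchors[parts[0]] = frozenset(int(x) for x in parts[1].split(","))
    seeds = []
    for rec in read_fasta(fasta_path):
        if rec.id not in anchors:
            raise ParseError(f"no anchor set for seed {rec.id!r}")
        seeds.append(QueryDomain(name=rec.id, sequence=rec.sequence,
                                 anchors=anchors[rec.id],
                                 provenance=rec.description))
    return seeds


def load_ift_query_set(fasta_path=None) -> IFTQuerySet:
    """The packaged 24-gene IFT/BBS query set grouped into four modules."""
    fasta_path = fasta_path or _data_path("ift_queries_synthetic.fasta")
    return query_set_from_records(read_fasta(fasta_path))


def load_profile_instances(fasta_path=None) -> dict:
    """Aligned instance sets per profile domain: {'AD': [seq, ...], ...}.

    Instance ids follow ``<DOMAIN>_<k>``; instances of one domain are
    equal-length (pre-aligned, gap columns removed).
    """
    fasta_path = fasta_path or _data_path("profile_instances_synthetic.fasta")
    out: dict[str, list[str]] = {}
    for rec in read_fasta(fasta_path):
        domain = rec.id.rsplit("_", 1)[0]
        out.setdefault(domain, []).append(rec.sequence)
    return out
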