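"""Synthetic proteomes with implanted domain homologs and known ground truth.

Every downstream stage of the survey is exercised on proteomes built here:
decoy proteins drawn i.i.d. from the background residue frequencies, domain
homologs produced by per-site substitution at a controlled divergence (with
DNA-contact anchors preserved or deliberately broken), and multi-species
series evolved along a known tree for phylogeny-recovery studies.

All generators are pure functions of their parameters and ``rng_seed``;
substitutions never introduce indels, so corrected PID and anchor counts
have closed-form expectations: an implant at divergence ``d`` with ``a``
anchors preserved out of ``L`` sites has expected PID
``100 * (1 - d * (L - a) / L)``, exact because the replacement residue is
drawn from the background *excluding* the current one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AMINO_ACIDS, BACKGROUND_FREQS
from .domain_search import QueryDomain, derive_seed
from .exceptions import ParameterError
from .io_formats import ProteinRecord

#: Truth labels carried by implants.
LABELS = ("RFX", "RFX_LIKE", "DECOY", "NONE")


@dataclass(frozen=True)
class ImplantSpec:
    """One domain homolog to implant: seed, divergence, anchor fate, flanks."""

    seed_domain: QueryDomain
    divergence: float
    preserve_anchors: bool = True
    flank_lengths: tuple = (100, 100)
    label: str = "RFX"

    def __post_init__(self):
        if not (0.0 <= self.divergence <= 1.0):
            raise ParameterError(f"divergence must be in [0, 1], got {self.divergence}")
        if min(self.flank_lengths) < 0:
            raise ParameterError("flank lengths must be non-negative")
        if self.label not in LABELS:
            raise ParameterError(f"unknown truth label {self.label!r}")


@dataclass(frozen=True)
class SyntheticProteome:
    """A species' records plus the truth table of implanted intervals."""

    species: str
    records: tuple
    truth: tuple  # (protein id, start, end, label), 0-based half-open

    def __post_init__(self):
        lengths = {r.id: len(r.sequence) for r in self.records}
        for pid, start, end, _label in self.truth:
            if not (0 <= start < end <= lengths[pid]):
                raise ParameterError(f"truth interval outside protein {pid!r}")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _substitute(rng: np.random.Generator, residue: str) -> str:
    """Replace a residue by a different one, proportional to background."""
    cur = AMINO_ACIDS.index(residue) if residue in AMINO_ACIDS else None
    p = BACKGROUND_FREQS.copy()
    if cur is not None:
        p[cur] = 0.0
    p /= p.sum()
    return AMINO_ACIDS[int(rng.choice(20, p=p))]


def evolve_domain(seed: QueryDomain, divergence: float, preserve_anchors: bool,
                  rng_seed: int) -> str:
    """Diverge a seed domain by independent per-site substitution.

    Each position is substituted with probability ``divergence`` to a
    *different* residue drawn from the background; anchor positions are never
    touched when ``preserve_anchors`` is set.  Length is preserved (no
    indels).
    """
    if not (0.0 <= divergence <= 1.0):
        raise ParameterError(f"divergence must be in [0, 1], got {divergence}")
    rng = np.random.default_rng(rng_seed)
    out = list(seed.sequence)
    hit = rng.random(len(out)) < divergence
    for pos in np.nonzero(hit)[0]:
        if preserve_anchors and int(pos) in seed.anchors:
            continue
        out[int(pos)] = _substitute(rng, out[int(pos)])
    return "".join(out)


def simulate_proteome(species: str, n_decoys: int, implants, decoy_length_range,
                      rng_seed: int) -> SyntheticProteome:
    """Build one proteome: background decoys plus flanked domain implants."""
    if n_decoys < 0:
        raise ParameterError("n_decoys must be non-negative")
    lo, hi = decoy_length_range
    if not (0 < lo <= hi):
        raise ParameterError("decoy_length_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(rng_seed)
    records = []
    truth = []
    for k, spec in enumerate(implants):
        domain = evolve_domain(spec.seed_domain, spec.divergence,
                               spec.preserve_anchors,
                               derive_seed(rng_seed, "implant", k))
        left, right = spec.flank_lengths
        seq = _random_peptide(rng, left) + domain + _random_peptide(rng, right)
        pid = f"{species}_implant{k + 1}"
        records.append(ProteinRecord(pid, species, seq,
                                     f"implant {spec.seed_domain.name} "
                                     f"d={spec.divergence}"))
        truth.append((pid, left, left + len(domain), spec.label))
    for k in range(n_decoys):
        length = int(rng.integers(lo, hi + 1))
        pid = f"{species}_decoy{k + 1}"
        records.append(ProteinRecord(pid, species, _random_peptide(rng, length),
                                     "background decoy"))
    return SyntheticProteome(species=species, records=tuple(records),
                             truth=tuple(truth))


def _evolve_branch(rng: np.random.Generator, sequence: str, anchors,
                   branch_length: float) -> str:
    """Poisson substitution events on non-anchor sites along one branch."""
    sites = [i for i in range(len(sequence)) if i not in anchors]
    if not sites:
        return sequence
    n_events = int(rng.poisson(branch_length * len(sites)))
    out = list(sequence)
    for _ in range(n_events):
        pos = sites[int(rng.integers(len(sites)))]
        out[pos] = _substitute(rng, out[pos])
    return "".join(out)


def simulate_clade_series(tree, seed_domain: QueryDomain, rng_seed: int,
                          n_decoys: int = 20,
                          decoy_length_range=(200, 400)) -> dict:
    """Evolve a domain along a tree; return one proteome per leaf.

    ``tree`` is a dendropy Tree whose edge lengths are expected substitutions
    per (non-anchor) site under the same replacement process as
    :func:`evolve_domain`.  Anchors are preserved throughout.  Negative
    branch lengths are rejected; zero-length branches copy the domain
    unchanged.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise ParameterError("tree must be a dendropy.Tree")
    rng = np.random.default_rng(rng_seed)
    sequences = {}

    def recurse(node, seq):
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 0.0
            if bl < 0:
                raise ParameterError(f"negative branch length {bl}")
            child_seq = _evolve_branch(rng, seq, seed_domain.anchors, bl)
            if child.is_leaf():
                sequences[child.taxon.label] = child_seq
            else:
                recurse(child, child_seq)

    recurse(tree.seed_node, seed_domain.sequence)
    proteomes = {}
    for leaf, seq in sorted(sequences.items()):
        leaf_domain = QueryDomain(name=f"{leaf}_domain", sequence=seq,
                                  anchors=seed_domain.anchors)
        spec = ImplantSpec(seed_domain=leaf_domain, divergence=0.0,
                           preserve_anchors=True, label="RFX")
        proteomes[leaf] = simulate_proteome(leaf, n_decoys, [spec],
                                            decoy_length_range,
                                            derive_seed(rng_seed, "leaf", leaf))
    return proteomes


def random_proteins(n: int, length_range, rng_seed: int,
                    species: str = "null") -> list:
    """Pure background decoy proteins (the null model for calibration tests)."""
    rng = np.random.default_rng(rng_seed)
    lo, hi = length_range
    return [
        ProteinRecord(f"{species}_decoy{k + 1}", species,
                      _random_peptide(rng, int(rng.integers(lo, hi + 1))))
        for k in range(n)
    ]
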