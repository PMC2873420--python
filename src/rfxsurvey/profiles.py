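"""Position-specific scoring profiles for the non-DBD RFX domains.

The activation (AD), B, C, D and dimerization (DD) domains are detected with
ungapped log-odds profiles built from small aligned instance sets: column
score ``ln((count + pc * b_r) / ((n + pc) * b_r))`` with pseudocount weight
``pc`` against background frequencies ``b``.  Acceptance thresholds are
calibrated empirically as a high quantile of best-window scores over random
background proteins.  Together with the DBD call from the domain search this
yields ordered architecture strings such as ``AD-DBD-B-C-DD``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .align import AMINO_ACIDS, BACKGROUND_FREQS, encode
from .exceptions import InputError, ParameterError
from .io_formats import ProteinRecord
from .synthetic import random_proteins

DOMAIN_NAMES = ("AD", "B", "C", "D", "DD")


@dataclass(frozen=True)
class DomainProfile:
    """Ungapped per-position log-odds profile with a calibrated threshold."""

    name: str
    columns: np.ndarray  # (length, 20) float
    score_threshold: float = np.inf

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=float)
        if cols.ndim != 2 or cols.shape[1] != 20 or cols.shape[0] < 5:
            raise ParameterError("profile needs >= 5 columns of 20 residue scores")
        if not np.isfinite(cols).all():
            raise ParameterError("profile scores must be finite")
        object.__setattr__(self, "columns", cols)

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    def with_threshold(self, threshold: float) -> "DomainProfile":
        return replace(self, score_threshold=float(threshold))


@dataclass(frozen=True)
class DomainAnnotation:
    """One accepted profile window on a protein (0-based half-open)."""

    protein_id: str
    domain: str
    interval: tuple
    score: float


def build_profile(instances, background=None, pseudocount: float = 1.0,
                  name: str = "domain") -> DomainProfile:
    """Log-odds profile from pre-aligned equal-length instances.

    'X' residues are ignored in the counts (the column's instance count drops
    accordingly); columns are pure functions of residue counts, so duplicated
    instance sets give identical profiles up to the count weights.
    """
    if len(instances) < 2:
        raise InputError("at least two instances are required")
    lengths = {len(s) for s in instances}
    if len(lengths) != 1:
        raise InputError(f"instances must have equal length, got {sorted(lengths)}")
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be positive")
    b = np.asarray(background if background is not None else BACKGROUND_FREQS,
                   dtype=float)
    b = b / b.sum()
    length = lengths.pop()
    cols = np.zeros((length, 20))
    encoded = [encode(s) for s in instances]
    for k in range(length):
        counts = np.zeros(20)
        for e in encoded:
            if e[k] < 20:  # skip 'X'
                counts[e[k]] += 1
        n = counts.sum()
        cols[k] = np.log((counts + pseudocount * b) / ((n + pseudocount) * b))
    return DomainProfile(name=name, columns=cols)


def window_scores(sequence: str, profile: DomainProfile) -> np.ndarray:
    """Sum of column scores at every offset (empty if the protein is shorter)."""
    idx = encode(sequence)
    L = profile.length
    if len(idx) < L:
        return np.zeros(0)
    # 'X' (index 20) scores 0: append a zero column to the score table
    table = np.hstack([profile.columns, np.zeros((L, 1))])
    windows = sliding_window_view(idx, L)
    return table[np.arange(L)[None, :], windows].sum(axis=1)


def scan_profile(protein: ProteinRecord, profile: DomainProfile) -> list:
    """Maximal non-overlapping windows scoring at or above the threshold.

    Windows are accepted greedily by descending score (ties: smaller offset),
    skipping any window overlapping an already accepted one.
    """
    scores = window_scores(protein.sequence, profile)
    if scores.size == 0:
        return []
    L = profile.length
    candidates = [(float(s), o) for o, s in enumerate(scores)
                  if s >= profile.score_threshold]
    candidates.sort(key=lambda c: (-c[0], c[1]))
    taken: list[tuple[int, int]] = []
    out = []
    for s, o in candidates:
        if any(o < e and o + L > b for b, e in taken):
            continue
        taken.append((o, o + L))
        out.append(DomainAnnotation(protein.id, profile.name, (o, o + L), s))
    out.sort(key=lambda a: a.interval)
    return out


def calibrate_threshold(profile: DomainProfile, background=None,
                        n_null: int = 1000, quantile: float = 0.99,
                        rng_seed: int = 0, null_length: int = 300) -> float:
    """Null-quantile threshold: the ``quantile`` of best-window scores over
    ``n_null`` random background proteins of ``null_length`` residues."""
    if n_null < 1000:
        raise ParameterError("n_null must be at least 1000")
    if not (0 < quantile <= 1):
        raise ParameterError("quantile must be in (0, 1]")
    null = random_proteins(n_null, (null_length, null_length), rng_seed)
    best = np.array([window_scores(p.sequence, profile).max() for p in null])
    return float(np.quantile(best, quantile, method="higher"))


def calibrate(profile: DomainProfile, **kwargs) -> DomainProfile:
    """Convenience: return the profile with its calibrated threshold set."""
    return profile.with_threshold(calibrate_threshold(profile, **kwargs))


def architecture(protein: ProteinRecord, profiles, dbd_call=None) -> str:
    """Ordered architecture string, e.g. ``AD-DBD-B-C-DD``.

    Profile annotations and the (optional) DBD hit from the domain search are
    merged; overlaps are resolved by keeping the higher score (the DBD, whose
    score is on the alignment scale, always wins against profile windows it
    overlaps).  Domains absent from the protein are simply omitted.
    """
    annos: list[DomainAnnotation] = []
    for prof in sorted(profiles, key=lambda p: p.name):
        annos.extend(scan_profile(protein, prof))
    if dbd_call is not None:
        annos.append(DomainAnnotation(protein.id, "DBD",
                                      dbd_call.alignment.target_interval,
                                      float("inf")))
    annos.sort(key=lambda a: (-a.score, a.interval, a.domain))
    kept: list[DomainAnnotation] = []
    for a in annos:
        if any(a.interval[0] < k.interval[1] and a.interval[1] > k.interval[0]
               for k in kept):
            continue
        kept.append(a)
    kept.sort(key=lambda a: a.interval)
    return "-".join(a.domain for a in kept)
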