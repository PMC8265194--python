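"""Structure-derived quantities for ASO design: target-site accessibility and
ASO:target binding energy.

Accessibility is the probability that a region of the folded target RNA is
unpaired and therefore available for hybridisation. The default backend
computes exact per-base unpaired probabilities from a McCaskill-style
partition function over secondary structures, scored with a simple
base-pair-additive energy model (G:C, A:U and G:U wobble pairs; minimum
hairpin loop of 3) and restricted to a local fold window with a maximum
pairing span, in the spirit of local-folding tools. The backend is a
contract: any object with an ``unpaired_profile(seq)`` method can stand in,
so external folding engines (e.g. ViennaRNA) can be plugged in; an adapter
is provided when the ``RNA`` bindings are importable.

Binding energy combines duplex formation with the cost of opening target
structure:

    dG_bind = dG_duplex + dG_open
    dG_duplex = initiation + sum of nearest-neighbor stack terms over the
                fully complementary ASO:target duplex
    dG_open = -RT * ln(mean unpaired probability over the target site)

at 37 degrees C. More negative means stronger net binding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Protocol

import numpy as np

from .records import normalize_sequence

logger = logging.getLogger(__name__)

#: Gas constant times temperature at 37 C, kcal/mol.
RT_37C = 0.6163

#: Floor applied to the mean unpaired probability before taking the log, so a
#: fully structured site yields a large but finite opening penalty.
MIN_UNPAIRED_PROB = 1e-6

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_HAIRPIN_LOOP = 3

#: Base-pair formation energies for the folding model, kcal/mol.
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement in the RNA alphabet."""
    seq = normalize_sequence(seq)
    return "".join(WC_COMPLEMENT[b] for b in reversed(seq))


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIR_ENERGY


class AccessibilityBackend(Protocol):
    """Contract for accessibility backends."""

    backend_id: str

    def unpaired_profile(self, seq: str) -> np.ndarray:
        """Per-base unpaired probability, one value in [0, 1] per base."""
        ...


@dataclass
class AccessibilityProfile:
    """Per-base unpaired probabilities over a sequence region."""

    values: np.ndarray
    backend_id: str
    fold_window: int | None = None
    max_span: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("unpaired probabilities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass(frozen=True)
class DuplexEnergy:
    """Free-energy change of ASO:target hybridisation, kcal/mol."""

    value: float
    method_id: str
    dG_duplex: float = 0.0
    dG_open: float = 0.0


def _window_pair_probs(seq: str, max_span: int) -> np.ndarray:
    """Exact base-pair probability matrix for one fold window.

    Inside-outside over the non-crossing structure ensemble with Boltzmann
    weight exp(-E/RT) per pair; pairs spanning more than ``max_span`` bases
    are forbidden.
    """
    n = len(seq)
    w = np.zeros((n, n))
    for i in range(n):
        jmax = min(n - 1, i + max_span)
        for j in range(i + MIN_HAIRPIN_LOOP + 1, jmax + 1):
            if _can_pair(seq[i], seq[j]):
                w[i, j] = math.exp(-PAIR_ENERGY[(seq[i], seq[j])] / RT_37C)
    # Inside. Z[i, j] = partition function over s[i..j-1] (empty interval 1);
    # Zb[i, j] = partition over s[i..j] given that (i, j) is paired.
    Z = np.ones((n + 1, n + 1))
    Zb = np.zeros((n, n))
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            last = j - 1
            zb = w[i:last, last] * Z[i + 1 : last + 1, last]
            Zb[i:last, last] = zb
            Z[i, j] = Z[i, last] + float(np.dot(Z[i, i:last], zb))
    Ztot = Z[0, n]
    # Outside, widest span first; an enclosing pair (h, l) contributes to a
    # pair (i, j) exactly when it is the innermost pair around it, in which
    # case the region between them factors as Z[h+1, i] * Z[j+1, l].
    # Ob(i, j) is the partition over everything outside pair (i, j);
    # A(h, l) = Ob(h, l) * w(h, l) accumulates processed (wider) pairs.
    Zup = np.zeros((n, n))  # Zup[a, b] = Z[a+1, b] for a < b, else 0
    for a in range(n):
        Zup[a, a + 1 :] = Z[a + 1, a + 1 : n + 1][: n - a - 1]
    ext = np.outer(Z[0, :n], Z[1 : n + 1, n])  # ext[i, j] = Z[0,i] * Z[j+1,n]
    A = np.zeros((n, n))
    P = np.zeros((n, n))
    ii, jj = np.nonzero(Zb)
    spans = jj - ii
    have_wider = False
    for s in sorted(set(spans.tolist()), reverse=True):
        sel = spans == s
        B = Zup.T @ A @ Zup.T if have_wider else None
        for i, j in zip(ii[sel], jj[sel]):
            ob = ext[i, j] + (B[i, j] if B is not None else 0.0)
            P[i, j] = Zb[i, j] * ob / Ztot
            A[i, j] = ob * w[i, j]
        have_wider = True
    return P


@dataclass
class PartitionAccessibility:
    """In-house local-fold partition-function accessibility backend.

    The sequence is folded in overlapping windows of ``fold_window`` bases
    (step ``fold_window // 2``); each base's unpaired probability is the mean
    over all windows covering it. Within a window probabilities are exact for
    the pair-additive energy model. Profiles are cached per sequence.
    """

    fold_window: int = 80
    max_span: int = 40
    backend_id: str = "inhouse-partition"
    _cache: dict = field(default_factory=dict, repr=False)

    def unpaired_profile(self, seq: str) -> np.ndarray:
        seq = normalize_sequence(seq)
        cached = self._cache.get(seq)
        if cached is not None:
            return cached
        n = len(seq)
        win = min(self.fold_window, n)
        step = max(1, win // 2)
        starts = list(range(0, max(n - win, 0) + 1, step))
        if starts[-1] != n - win:
            starts.append(n - win)
        acc = np.zeros(n)
        cov = np.zeros(n)
        for s in starts:
            sub = seq[s : s + win]
            P = _window_pair_probs(sub, self.max_span)
            unpaired = 1.0 - (P.sum(axis=0) + P.sum(axis=1))
            acc[s : s + win] += unpaired
            cov[s : s + win] += 1.0
        profile = np.clip(acc / cov, 0.0, 1.0)
        self._cache[seq] = profile
        return profile


class ViennaAccessibility:
    """Adapter for the ViennaRNA partition function (optional backend).

    Uses the full-length equilibrium ensemble; values differ from the
    in-house backend but orderings on simple panels agree.
    """

    backend_id = "viennarna"

    def __init__(self) -> None:
        import RNA  # deferred: optional dependency

        self._RNA = RNA

    def unpaired_profile(self, seq: str) -> np.ndarray:
        seq = normalize_sequence(seq)
        fc = self._RNA.fold_compound(seq)
        fc.pf()
        bpp = np.asarray(fc.bpp())[1:, 1:]  # 1-indexed matrix
        paired = bpp.sum(axis=0) + bpp.sum(axis=1)
        return np.clip(1.0 - paired, 0.0, 1.0)


def accessibility(
    sequence: str,
    region_start: int,
    region_end: int,
    backend: AccessibilityBackend | None = None,
) -> float:
    """Mean unpaired probability over a 1-based inclusive region."""
    sequence = normalize_sequence(sequence)
    if not (1 <= region_start <= region_end <= len(sequence)):
        raise ValueError(
            f"region {region_start}-{region_end} outside sequence of length {len(sequence)}"
        )
    backend = backend or PartitionAccessibility()
    profile = backend.unpaired_profile(sequence)
    return float(np.mean(profile[region_start - 1 : region_end]))


@dataclass
class NNTable:
    """Nearest-neighbor stacking table, keyed by the 5'->3' target-strand
    dinucleotide of a Watson-Crick stack."""

    stacks: dict[str, float]
    initiation: float
    version: str = "1"

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NNTable":
        stacks: dict[str, float] = {}
        initiation = 0.0
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("key"):
                continue
            key, value = line.split("\t")
            if key == "init":
                initiation = float(value)
            else:
                stacks[key] = float(value)
        return cls(stacks=stacks, initiation=initiation)

    @classmethod
    def default(cls) -> "NNTable":
        ref = importlib_resources.files("exonskip.resources") / "nn_stack_rna.tsv"
        with importlib_resources.as_file(ref) as path:
            return cls.from_tsv(path)


_DEFAULT_NN: NNTable | None = None


def default_nn_table() -> NNTable:
    global _DEFAULT_NN
    if _DEFAULT_NN is None:
        _DEFAULT_NN = NNTable.default()
    return _DEFAULT_NN


def duplex_energy(target_site: str, table: NNTable | None = None) -> float:
    """Stacking free energy of the fully complementary duplex on a target
    site, kcal/mol: initiation plus one nearest-neighbor term per
    dinucleotide step of the target strand."""
    target_site = normalize_sequence(target_site)
    if len(target_site) < 1:
        raise ValueError("empty target site")
    table = table or default_nn_table()
    total = table.initiation
    for i in range(len(target_site) - 1):
        total += table.stacks[target_site[i : i + 2]]
    return total


def binding_energy(
    aso: str,
    flanked_target: str,
    site_start: int,
    site_end: int,
    backend: AccessibilityBackend | None = None,
    table: NNTable | None = None,
    mode: str = "structure_competition",
) -> DuplexEnergy:
    """Net ASO binding energy to a site within its flanked target sequence.

    ``flanked_target`` is the target site plus up to 50 bases of natural
    sequence on each side (truncated at transcript ends); ``site_start`` /
    ``site_end`` are 1-based inclusive coordinates of the site within it. The
    ASO must be the exact reverse complement of the site.

    ``mode`` selects duplex-only (``"duplex_only"``) or the default
    structure-competition model, which adds the free-energy cost of opening
    the site out of the target's own secondary structure.
    """
    aso = normalize_sequence(aso)
    flanked_target = normalize_sequence(flanked_target)
    if not (1 <= site_start <= site_end <= len(flanked_target)):
        raise ValueError(
            f"site {site_start}-{site_end} outside flanked target of length {len(flanked_target)}"
        )
    site = flanked_target[site_start - 1 : site_end]
    if reverse_complement(site) != aso:
        raise ValueError("ASO is not the reverse complement of the designated target site")
    table = table or default_nn_table()
    dG_dup = duplex_energy(site, table)
    if mode == "duplex_only":
        return DuplexEnergy(value=dG_dup, method_id="nn-duplex", dG_duplex=dG_dup)
    backend = backend or PartitionAccessibility()
    p_open = max(
        accessibility(flanked_target, site_start, site_end, backend), MIN_UNPAIRED_PROB
    )
    dG_open = -RT_37C * math.log(p_open)
    return DuplexEnergy(
        value=dG_dup + dG_open,
        method_id=f"nn-duplex+open[{backend.backend_id}]",
        dG_duplex=dG_dup,
        dG_open=dG_open,
    )
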