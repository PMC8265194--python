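"""Feature engineering for exon-skipping ASO efficacy prediction.

Each feature is a pure function of the ASO, its target-exon context (the exon
plus up to 200 bases of upstream and downstream intron), the experimental
concentration, and static resources (the nearest-neighbor table, an NI k-mer
score table, an accessibility backend). The catalog covers the sequence,
positional, thermodynamic and splicing-signal features known to influence
skipping efficacy; a registry makes the set open-ended so additional
candidate features can be plugged in without touching the engine.

Coordinates are 1-based on the exon; exon position 1 is the first exonic base
after the splice acceptor site.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from . import thermo
from .records import normalize_sequence

logger = logging.getLogger(__name__)

#: The concentration feature is forced into every model.
CONCENTRATION_FEATURE = "ASO concentration"

MAX_INTRON_FLANK = 200
BINDING_FLANK = 50


@dataclass
class TargetContext:
    """A target exon with its intron flanks.

    ``upstream_intron`` is the 3' end of the upstream intron (its last base
    abuts the splice acceptor); ``downstream_intron`` starts at the splice
    donor. Flanks longer than 200 bases are truncated to the 200 bases
    nearest the exon.
    """

    exon_seq: str
    upstream_intron: str = ""
    downstream_intron: str = ""
    gene: str = ""
    exon_number: int | None = None

    def __post_init__(self) -> None:
        self.exon_seq = normalize_sequence(self.exon_seq)
        self.upstream_intron = (
            normalize_sequence(self.upstream_intron) if self.upstream_intron else ""
        )
        self.downstream_intron = (
            normalize_sequence(self.downstream_intron) if self.downstream_intron else ""
        )
        if len(self.upstream_intron) > MAX_INTRON_FLANK:
            logger.warning("upstream intron longer than %d bases; truncating", MAX_INTRON_FLANK)
            self.upstream_intron = self.upstream_intron[-MAX_INTRON_FLANK:]
        if len(self.downstream_intron) > MAX_INTRON_FLANK:
            logger.warning("downstream intron longer than %d bases; truncating", MAX_INTRON_FLANK)
            self.downstream_intron = self.downstream_intron[:MAX_INTRON_FLANK]

    @property
    def full_sequence(self) -> str:
        """Upstream intron + exon + downstream intron, the folding substrate."""
        return self.upstream_intron + self.exon_seq + self.downstream_intron

    @property
    def exon_offset(self) -> int:
        """0-based offset of exon position 1 within :attr:`full_sequence`."""
        return len(self.upstream_intron)

    def check_site(self, site_start: int, site_end: int) -> None:
        if not (1 <= site_start <= site_end <= len(self.exon_seq)):
            raise ValueError(
                f"target site {site_start}-{site_end} outside exon of length {len(self.exon_seq)}"
            )


@dataclass
class NiScoreTable:
    """Lookup table of per-k-mer NI splicing-relevance scores."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        self.scores = {normalize_sequence(k): float(v) for k, v in self.scores.items()}
        lengths = {len(k) for k in self.scores}
        if len(lengths) > 1:
            raise ValueError(f"NI table k-mers have mixed lengths: {sorted(lengths)}")

    @property
    def k(self) -> int:
        return len(next(iter(self.scores))) if self.scores else 0

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NiScoreTable":
        scores: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kmer, value = line.split("\t")
            if kmer.lower() in {"kmer", "k-mer"}:
                continue
            scores[kmer] = float(value)
        return cls(scores=scores)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tscore\n")
            for kmer in sorted(self.scores):
                fh.write(f"{kmer}\t{self.scores[kmer]!r}\n")


@dataclass
class ThermoResources:
    """Shared static resources for thermodynamic features.

    The accessibility backend caches unpaired-probability profiles per
    sequence, so exon-level quantities are folded once per context however
    many candidate ASOs are evaluated on it.
    """

    backend: thermo.AccessibilityBackend = field(default_factory=thermo.PartitionAccessibility)
    nn_table: thermo.NNTable = field(default_factory=thermo.default_nn_table)
    binding_mode: str = "structure_competition"


# ---------------------------------------------------------------------------
# Elementary feature computations
# ---------------------------------------------------------------------------

def gc_count(aso_sequence: str) -> int:
    """Total number of G and C bases in the ASO sequence."""
    seq = normalize_sequence(aso_sequence)
    return seq.count("G") + seq.count("C")


def _pct_gc(seq: str) -> float:
    if not seq:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def acp(context: TargetContext, site_start: int, site_end: int) -> int:
    """Distance in bases from the splice acceptor site to the center of the
    target site (exon coordinate of the site midpoint; even-length sites
    round toward the acceptor)."""
    context.check_site(site_start, site_end)
    return (site_start + site_end) // 2


def pct_gc_blocked(context: TargetContext, site_start: int, site_end: int) -> float:
    """Remaining %GC of the target exon when the ASO blocks its site."""
    context.check_site(site_start, site_end)
    remaining = context.exon_seq[: site_start - 1] + context.exon_seq[site_end:]
    if not remaining:
        logger.warning("ASO site covers the whole exon; remaining %%GC defined as 0")
        return 0.0
    return _pct_gc(remaining)


def exon_v_intron_gc(context: TargetContext, site_start: int, site_end: int) -> float:
    """Blocked-exon %GC divided by the %GC of the upstream 200-base intron.

    Returns NaN (flagging the record) when the upstream intron is absent or
    GC-free.
    """
    if not context.upstream_intron:
        logger.warning("no upstream intron sequence; exon/intron GC ratio undefined")
        return float("nan")
    intron_gc = _pct_gc(context.upstream_intron)
    if intron_gc == 0.0:
        logger.warning("upstream intron has zero GC; exon/intron GC ratio undefined")
        return float("nan")
    return pct_gc_blocked(context, site_start, site_end) / intron_gc


def ni_score_per_base(context: TargetContext, table: NiScoreTable) -> float:
    """Cumulative NI score over all overlapping exon k-mers, divided by the
    number of exon bases."""
    if not table.scores:
        raise ValueError("empty NI score table")
    k = table.k
    exon = context.exon_seq
    if k > len(exon):
        logger.warning("NI k-mer length %d exceeds exon length %d; score 0", k, len(exon))
        return 0.0
    total = 0.0
    for i in range(len(exon) - k + 1):
        total += table.scores.get(exon[i : i + k], 0.0)
    return total / len(exon)


def acc_last(
    context: TargetContext,
    site_start: int,
    site_end: int,
    n: int,
    resources: ThermoResources,
) -> float:
    """Mean predicted accessibility of the last ``n`` bases (3' end) of the
    target site, folded in the exon-plus-flanks context."""
    context.check_site(site_start, site_end)
    site_len = site_end - site_start + 1
    if site_len < n:
        logger.warning("site length %d < %d; accessibility over whole site", site_len, n)
        n = site_len
    off = context.exon_offset
    start = off + site_end - n + 1  # 1-based on full_sequence
    end = off + site_end
    return thermo.accessibility(context.full_sequence, start, end, resources.backend)


def binding_dG_50flank(
    context: TargetContext,
    site_start: int,
    site_end: int,
    aso_sequence: str,
    resources: ThermoResources,
) -> float:
    """Predicted ASO:target binding energy over the site plus 50-base flanks
    of natural context sequence (truncated at the ends of the available
    flanked exon), kcal/mol."""
    context.check_site(site_start, site_end)
    full = context.full_sequence
    off = context.exon_offset
    lo = max(0, off + site_start - 1 - BINDING_FLANK)  # 0-based inclusive
    hi = min(len(full), off + site_end + BINDING_FLANK)  # 0-based exclusive
    flanked = full[lo:hi]
    rel_start = off + site_start - 1 - lo + 1
    rel_end = off + site_end - lo
    return thermo.binding_energy(
        aso_sequence,
        flanked,
        rel_start,
        rel_end,
        backend=resources.backend,
        table=resources.nn_table,
        mode=resources.binding_mode,
    ).value


def hash_noise(aso_sequence: str, salt: str = "decoy") -> float:
    """Deterministic pseudo-random value in [0, 1) derived from the ASO
    sequence. A pure function uncorrelated with efficacy, used as a negative
    control in feature-selection and importance experiments."""
    digest = hashlib.sha256((salt + normalize_sequence(aso_sequence)).encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

ComputeFn = Callable[[TargetContext, int, int, str, float, ThermoResources], float]


@dataclass(frozen=True)
class FeatureDefinition:
    """A named feature and its compute contract.

    ``fn`` receives ``(context, site_start, site_end, aso_sequence,
    concentration_uM, resources)`` and returns a float.
    """

    name: str
    description: str
    fn: ComputeFn
    chemistry_scope: str = "both"  # "PMO", "2OMe" or "both"


class FeatureRegistry:
    """Ordered, name-unique collection of feature definitions."""

    def __init__(self, definitions: Iterable[FeatureDefinition] = ()) -> None:
        self._defs: dict[str, FeatureDefinition] = {}
        for d in definitions:
            self.register(d)

    def register(self, definition: FeatureDefinition) -> None:
        if definition.name in self._defs:
            raise ValueError(f"duplicate feature name {definition.name!r}")
        self._defs[definition.name] = definition

    @property
    def names(self) -> list[str]:
        return list(self._defs)

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __getitem__(self, name: str) -> FeatureDefinition:
        return self._defs[name]

    def __len__(self) -> int:
        return len(self._defs)

    def subset(self, names: Iterable[str]) -> "FeatureRegistry":
        return FeatureRegistry(self._defs[n] for n in names)


def default_registry(
    ni_table: NiScoreTable | None = None,
    include_thermo: bool = True,
) -> FeatureRegistry:
    """The standard feature catalog.

    Thermodynamic features (accessibility, binding energy) and the NI score
    are included only when their resources are available/requested; the
    model-selection engine runs with any subset of the catalog.
    """
    defs = [
        FeatureDefinition(
            CONCENTRATION_FEATURE,
            "Concentration of oligomer used in the experiment (uM)",
            lambda ctx, s, e, aso, conc, res: float(conc),
        ),
        FeatureDefinition(
            "GCs (number of)",
            "Total GCs in ASO sequence",
            lambda ctx, s, e, aso, conc, res: float(gc_count(aso)),
        ),
        FeatureDefinition(
            "ACP",
            "Distance in bases from the splice acceptor site to the center of the target site",
            lambda ctx, s, e, aso, conc, res: float(acp(ctx, s, e)),
        ),
        FeatureDefinition(
            "%GC of exon when blocked by oligo",
            "Total remaining %GC of target exon sequence when blocked by the ASO",
            lambda ctx, s, e, aso, conc, res: pct_gc_blocked(ctx, s, e),
        ),
        FeatureDefinition(
            "Exon v intron %GC after blocking by oligo",
            "%GC in exon when blocked by oligo / %GC of the 200-base upstream intron",
            lambda ctx, s, e, aso, conc, res: exon_v_intron_gc(ctx, s, e),
        ),
        FeatureDefinition(
            "ASO length",
            "Length of the ASO in bases",
            lambda ctx, s, e, aso, conc, res: float(len(normalize_sequence(aso))),
        ),
        FeatureDefinition(
            "%GC of ASO",
            "GC percentage of the ASO sequence",
            lambda ctx, s, e, aso, conc, res: _pct_gc(normalize_sequence(aso)),
        ),
        FeatureDefinition(
            "Exon length",
            "Length of the target exon in bases",
            lambda ctx, s, e, aso, conc, res: float(len(ctx.exon_seq)),
        ),
    ]
    if ni_table is not None:
        defs.append(
            FeatureDefinition(
                "niscore_per_base",
                "Cumulative NI score divided by the number of exon bases",
                lambda ctx, s, e, aso, conc, res, _t=ni_table: ni_score_per_base(ctx, _t),
            )
        )
    if include_thermo:
        defs.extend(
            [
                FeatureDefinition(
                    "ACC_LAST15",
                    "Mean predicted accessibility of the 3' end of the target (last 15 bases)",
                    lambda ctx, s, e, aso, conc, res: acc_last(ctx, s, e, 15, res),
                ),
                FeatureDefinition(
                    "ACC_LAST8",
                    "Mean predicted accessibility of the 3' end of the target (last 8 bases)",
                    lambda ctx, s, e, aso, conc, res: acc_last(ctx, s, e, 8, res),
                ),
                FeatureDefinition(
                    "dG (50BaseFlanksAroundTarget)",
                    "Predicted ASO binding energy to the target site plus 50-base flanks",
                    lambda ctx, s, e, aso, conc, res: binding_dG_50flank(ctx, s, e, aso, res),
                ),
            ]
        )
    return FeatureRegistry(defs)


@dataclass
class FeatureVector:
    """Named numeric features for one (ASO, context, concentration) triple."""

    values: dict[str, float]
    complete: bool = True
    errors: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def compute_features(
    context: TargetContext,
    site_start: int,
    site_end: int,
    aso_sequence: str,
    concentration_uM: float,
    registry: FeatureRegistry,
    resources: ThermoResources | None = None,
) -> FeatureVector:
    """Evaluate every registered feature for one candidate.

    A feature that raises or returns a non-finite value marks the vector as
    incomplete (training excludes such vectors); the remaining features are
    still computed.
    """
    if concentration_uM <= 0:
        raise ValueError(f"concentration must be positive, got {concentration_uM}")
    resources = resources or ThermoResources()
    values: dict[str, float] = {}
    errors: list[str] = []
    for name in registry.names:
        try:
            v = float(registry[name].fn(context, site_start, site_end, aso_sequence,
                                        concentration_uM, resources))
        except Exception as exc:  # noqa: BLE001 - feature errors are data, not bugs
            logger.warning("feature %r failed: %s", name, exc)
            v = float("nan")
            errors.append(f"{name}: {exc}")
        if not math.isfinite(v):
            errors.append(f"{name}: non-finite value")
        values[name] = v
    return FeatureVector(values=values, complete=not errors, errors=errors)


def feature_table(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame (one row per vector)."""
    return pd.DataFrame([v.values for v in vectors])


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature z-scoring constants (population standard deviation).

    Constants are fitted on the training portion of each split only, never on
    validation or test rows, to avoid information leakage.
    """

    feature_names: list[str]
    mean_: np.ndarray
    scale_: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "Standardizer":
        if len(table) < 2:
            raise ValueError("need at least 2 rows to fit standardization constants")
        mean = table.mean(axis=0).to_numpy(dtype=float)
        scale = table.std(axis=0, ddof=0).to_numpy(dtype=float)
        constant = scale == 0.0
        if constant.any():
            names = [n for n, c in zip(table.columns, constant) if c]
            logger.warning("constant feature(s) %s; sd clamped to 1", names)
            scale = np.where(constant, 1.0, scale)
        return cls(list(table.columns), mean, scale)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [n for n in self.feature_names if n not in table.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        sub = table[self.feature_names]
        return (sub - self.mean_) / self.scale_

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.feature_names] * self.scale_ + self.mean_


def standardize_fit(table: pd.DataFrame) -> Standardizer:
    return Standardizer.fit(table)


def standardize_apply(table: pd.DataFrame, constants: Standardizer) -> pd.DataFrame:
    return constants.transform(table)
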