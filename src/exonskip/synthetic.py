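"""Synthetic benchmark generator with planted feature -> efficacy structure.

Generates random exon/intron contexts and ASO experiment records whose
skipping efficacy is a known noisy linear function of a chosen ("planted")
subset of features, so the whole model-selection protocol can be exercised
and its recovery behaviour measured without any external data.

The generative model: for record i with standardized planted features z_i,

    efficacy_i = clamp_[0,100]( beta0 + beta . z_i + Normal(0, sigma) )

Standardization is over the generated dataset (population moments), so the
coefficients beta are on a comparable scale regardless of each feature's
natural units. Clamping respects the percent scale of real measurements;
configurations used in tests keep the clamping rate below a couple of
percent so that linear recovery arguments remain valid.

Records are generated to satisfy the training-data inclusion criteria by
construction (absolute efficacy, positive concentration, reference cell
line, not EC50, sequential).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import (
    CONCENTRATION_FEATURE,
    FeatureDefinition,
    FeatureRegistry,
    TargetContext,
    compute_features,
    hash_noise,
)
from .records import AsoRecord, Chemistry, RecordSet, write_records
from .thermo import reverse_complement

logger = logging.getLogger(__name__)

#: Discrete experimental concentrations (uM) typical of cultured-cell
#: transfection series.
DEFAULT_CONCENTRATIONS = (0.1, 0.3, 1.0, 3.0, 10.0)

DECOY_FEATURE = "decoy_noise"


def decoy_definition(name: str = DECOY_FEATURE) -> FeatureDefinition:
    """A pure-noise negative-control feature: deterministic in the ASO
    sequence, independent of efficacy."""
    return FeatureDefinition(
        name,
        "Sequence-hash noise control, uncorrelated with efficacy",
        lambda ctx, s, e, aso, conc, res: hash_noise(aso),
    )


#: Feature names of the scaled-down protocol registry (8 features).
PROTOCOL_FEATURES = (
    CONCENTRATION_FEATURE,
    "GCs (number of)",
    "ACP",
    "%GC of exon when blocked by oligo",
    "Exon v intron %GC after blocking by oligo",
    "ASO length",
    "%GC of ASO",
    DECOY_FEATURE,
)


def protocol_registry() -> FeatureRegistry:
    """The 8-feature registry used by the scaled-down protocol experiments:
    concentration, six cheap sequence/positional features, and a pure-noise
    decoy. Thermodynamic features are deliberately excluded so experiments
    stay fast and their ground truth exact."""
    from .features import default_registry

    reg = default_registry(ni_table=None, include_thermo=False)
    reg.register(decoy_definition())
    return reg.subset(PROTOCOL_FEATURES)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_records: int = 300
    exon_length: tuple[int, int] = (80, 160)
    intron_length: int = 200
    gc_fraction: float = 0.5
    aso_length: tuple[int, int] = (18, 30)
    chemistry: Chemistry = Chemistry.PMO
    planted: Mapping[str, float] = field(
        default_factory=lambda: {
            CONCENTRATION_FEATURE: 8.0,
            "GCs (number of)": 12.0,
            "ACP": 8.0,
        }
    )
    beta0: float = 50.0
    sigma: float = 8.0
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    cell_type: str = "RD"
    seed: int = 0

    @property
    def planted_features(self) -> tuple[str, ...]:
        """Planted features other than the always-present concentration."""
        return tuple(n for n in self.planted if n != CONCENTRATION_FEATURE)


def _random_seq(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    p = [
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,  # C
        gc_fraction / 2,  # G
        (1 - gc_fraction) / 2,  # U
    ]
    return "".join(rng.choice(["A", "C", "G", "U"], size=length, p=p))


def random_context(
    length: int,
    gc_fraction: float = 0.5,
    seed: int | np.random.Generator | None = None,
    intron_length: int = 200,
) -> TargetContext:
    """Random exon of ``length`` bases with i.i.d. bases at the requested GC
    fraction, flanked by introns of ``intron_length`` bases."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must lie in [0, 1], got {gc_fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return TargetContext(
        exon_seq=_random_seq(rng, length, gc_fraction),
        upstream_intron=_random_seq(rng, intron_length, gc_fraction),
        downstream_intron=_random_seq(rng, intron_length, gc_fraction),
        gene="SYN",
    )


@dataclass
class SyntheticDataset:
    """A generated record set, its contexts, feature matrix and ground truth."""

    records: RecordSet
    contexts: list[TargetContext]
    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    truth: pd.DataFrame
    config: SyntheticConfig

    @property
    def clamping_rate(self) -> float:
        return float(self.truth["clamped"].mean())

    def context_for(self, record: AsoRecord) -> TargetContext:
        return self.contexts[record.target_exon - 1]

    def write(self, out_dir: str | Path) -> None:
        """Emit the canonical records TSV, the feature table and the
        ground-truth table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(self.records, out / "records.tsv")
        table = self.X.copy()
        table.insert(0, "aso_sequence", self.groups)
        table["efficacy_pct"] = self.y
        table.to_csv(out / "features.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def generate_dataset(
    cfg: SyntheticConfig, registry: FeatureRegistry | None = None
) -> SyntheticDataset:
    """Generate a dataset under ``cfg`` with known ground truth.

    Every record gets its own random context and target window; the feature
    matrix covers the full registry, while only the planted subset (plus
    concentration, when planted) drives the efficacy signal.
    """
    registry = registry or protocol_registry()
    missing = [n for n in cfg.planted if n not in registry]
    if missing:
        raise ValueError(f"planted feature(s) not in registry: {missing}")
    if cfg.sigma < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(cfg.seed)

    contexts: list[TargetContext] = []
    raw_rows: list[dict[str, float]] = []
    meta: list[tuple[str, int, int, float]] = []
    for i in range(cfg.n_records):
        exon_len = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        ctx = random_context(exon_len, cfg.gc_fraction, rng, cfg.intron_length)
        ctx.exon_number = i + 1
        aso_len = int(rng.integers(cfg.aso_length[0], cfg.aso_length[1] + 1))
        start = int(rng.integers(1, exon_len - aso_len + 2))
        end = start + aso_len - 1
        aso = reverse_complement(ctx.exon_seq[start - 1 : end])
        conc = float(rng.choice(cfg.concentrations))
        vec = compute_features(ctx, start, end, aso, conc, registry)
        contexts.append(ctx)
        raw_rows.append(vec.values)
        meta.append((aso, start, end, conc))

    X = pd.DataFrame(raw_rows)
    planted_names = list(cfg.planted)
    betas = np.array([cfg.planted[n] for n in planted_names])
    planted_X = X[planted_names].to_numpy(dtype=float)
    mu = planted_X.mean(axis=0)
    sd = planted_X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    z = (planted_X - mu) / sd
    signal = cfg.beta0 + z @ betas
    noise = rng.normal(0.0, cfg.sigma, size=cfg.n_records) if cfg.sigma > 0 else np.zeros(cfg.n_records)
    raw_eff = signal + noise
    efficacy = np.clip(raw_eff, 0.0, 100.0)
    clamped = raw_eff != efficacy
    if clamped.mean() > 0.02:
        logger.warning("efficacy clamping rate %.1f%% exceeds 2%%", 100 * clamped.mean())

    records = []
    for i, (aso, start, end, conc) in enumerate(meta):
        records.append(
            AsoRecord(
                aso_sequence=aso,
                chemistry=cfg.chemistry,
                concentration_uM=conc,
                efficacy_pct=float(efficacy[i]),
                gene="SYN",
                species="synthetic",
                target_exon=i + 1,
                target_start=start,
                target_end=end,
                efficacy_is_absolute=True,
                efficacy_is_ec50=False,
                is_sequential=True,
                cell_type=cfg.cell_type,
                source="synthetic",
            )
        )
    truth = pd.DataFrame(
        {
            **{f"z[{n}]": z[:, j] for j, n in enumerate(planted_names)},
            "signal": signal,
            "noise": noise,
            "efficacy_pct": efficacy,
            "clamped": clamped,
        }
    )
    truth.attrs["betas"] = dict(cfg.planted)
    truth.attrs["beta0"] = cfg.beta0
    groups = np.array([r.normalized_sequence for r in records], dtype=object)
    return SyntheticDataset(
        records=RecordSet(records, {"generator": "synthetic", "seed": cfg.seed}),
        contexts=contexts,
        X=X,
        y=efficacy,
        groups=groups,
        truth=truth,
        config=cfg,
    )


def signal_variance(cfg: SyntheticConfig, n: int = 10_000, seed: int | None = None) -> float:
    """Monte-Carlo estimate of the variance of the noiseless efficacy signal
    (before clamping) under ``cfg``."""
    sim_cfg = replace(cfg, n_records=n, sigma=0.0, seed=cfg.seed if seed is None else seed)
    ds = generate_dataset(sim_cfg)
    return float(np.var(ds.truth["signal"], ddof=0))


def noise_ceiling(cfg: SyntheticConfig, n: int = 10_000, seed: int | None = None) -> float:
    """Expected maximal R-squared of any predictor under ``cfg``:
    Var(signal) / (Var(signal) + sigma^2), estimated by simulation."""
    var_signal = signal_variance(cfg, n=n, seed=seed)
    return var_signal / (var_signal + cfg.sigma**2)


def calibrate_sigma(
    cfg: SyntheticConfig, target_ceiling: float, n: int = 10_000, seed: int | None = None
) -> SyntheticConfig:
    """Return a config whose noise sd puts the noise ceiling at
    ``target_ceiling``."""
    if not 0.0 < target_ceiling <= 1.0:
        raise ValueError("target ceiling must lie in (0, 1]")
    var_signal = signal_variance(cfg, n=n, seed=seed)
    sigma = float(np.sqrt(var_signal * (1.0 - target_ceiling) / target_ceiling))
    return replace(cfg, sigma=sigma)
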