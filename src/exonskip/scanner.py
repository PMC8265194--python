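"""Sliding-window prediction of exon-skipping efficacy along a target exon.

Given an exon with its 200-base intron flanks, an ASO length and chemistry,
every contiguous window of that length inside the exon is a candidate target
site; the candidate ASO is its reverse complement. The trained model scores
each window at a chemistry-typical concentration (3 uM for PMO, 0.1 uM for
2OMe, unless overridden) and a centered 15-base moving average smooths the
per-window profile. Windows never span the exon/intron junctions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .features import FeatureRegistry, TargetContext, ThermoResources, compute_features
from .model import TrainedEfficacyModel
from .records import Chemistry
from .thermo import reverse_complement

logger = logging.getLogger(__name__)

#: Chemistry-typical assay concentrations (uM) applied when the user gives none.
DEFAULT_CONCENTRATION = {Chemistry.PMO: 3.0, Chemistry.TWO_OME: 0.1}

SMOOTHING_WINDOW = 15


@dataclass
class ScanRequest:
    """One scan of an exon for candidate ASOs."""

    context: TargetContext
    model: TrainedEfficacyModel
    registry: FeatureRegistry
    aso_length: int = 25
    chemistry: Chemistry = Chemistry.PMO
    concentration_uM: float | None = None
    resources: ThermoResources = field(default_factory=ThermoResources)

    def __post_init__(self) -> None:
        self.chemistry = Chemistry.parse(self.chemistry)
        if self.aso_length > len(self.context.exon_seq):
            raise ValueError(
                f"ASO length {self.aso_length} exceeds exon length {len(self.context.exon_seq)}"
            )
        if self.concentration_uM is None:
            self.concentration_uM = DEFAULT_CONCENTRATION[self.chemistry]
        if self.concentration_uM <= 0:
            raise ValueError("concentration must be positive")
        model_chem = self.model.spec.chemistry
        if model_chem is not None and Chemistry.parse(model_chem) is not self.chemistry:
            raise ValueError(
                f"model was trained for {model_chem}, request is for {self.chemistry.value}"
            )
        for flank, name in (
            (self.context.upstream_intron, "upstream"),
            (self.context.downstream_intron, "downstream"),
        ):
            if len(flank) < 200:
                logger.warning(
                    "%s intron flank is %d bases (< 200); near-edge features lose context",
                    name, len(flank),
                )


@dataclass
class ScanResult:
    """Per-window predictions plus the smoothed profile.

    ``window_start`` is the 1-based exon coordinate of the first blocked
    base; profiles are indexed by window start.
    """

    table: pd.DataFrame  # window_start, window_end, aso_sequence, predicted_efficacy, smoothed
    metadata: dict

    def __len__(self) -> int:
        return len(self.table)


def enumerate_windows(context: TargetContext, aso_length: int) -> pd.DataFrame:
    """All candidate target sites of ``aso_length`` fully inside the exon,
    with the candidate ASO sequence (reverse complement, RNA alphabet)."""
    exon = context.exon_seq
    if aso_length > len(exon):
        raise ValueError(f"ASO length {aso_length} exceeds exon length {len(exon)}")
    if aso_length < 1:
        raise ValueError("ASO length must be >= 1")
    rows = []
    for start in range(1, len(exon) - aso_length + 2):
        end = start + aso_length - 1
        rows.append(
            {
                "window_start": start,
                "window_end": end,
                "aso_sequence": reverse_complement(exon[start - 1 : end]),
            }
        )
    return pd.DataFrame(rows)


def moving_average(series: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Centered moving average; positions where the full window does not fit
    are NaN (never zero-padded)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if window > len(s):
        logger.warning("smoothing window %d exceeds series length %d", window, len(s))
        return np.full(len(s), np.nan)
    return s.rolling(window, center=True, min_periods=window).mean().to_numpy()


def scan(request: ScanRequest) -> ScanResult:
    """Predict per-window skipping efficacy along the exon.

    Window features are computed with shared resources, so context-level
    quantities (the folded accessibility profile, exon-wide scores) are
    evaluated once and reused across windows. Raw predictions are reported
    as-is (they may fall below 0); any display flooring belongs to plotting.
    """
    windows = enumerate_windows(request.context, request.aso_length)
    vectors = []
    for row in windows.itertuples(index=False):
        vec = compute_features(
            request.context,
            row.window_start,
            row.window_end,
            row.aso_sequence,
            request.concentration_uM,
            request.registry,
            request.resources,
        )
        vectors.append(vec.values)
    X = pd.DataFrame(vectors)
    predictions = request.model.predict(X)
    table = windows.copy()
    table["predicted_efficacy"] = predictions
    table["smoothed"] = moving_average(predictions, SMOOTHING_WINDOW)
    metadata = {
        "aso_length": request.aso_length,
        "chemistry": request.chemistry.value,
        "concentration_uM": request.concentration_uM,
        "exon_length": len(request.context.exon_seq),
        "smoothing_window": SMOOTHING_WINDOW,
        "model_features": list(request.model.spec.feature_names),
        "model_hyperparameters": {
            "C": request.model.spec.C,
            "gamma": request.model.spec.gamma,
            "epsilon": request.model.spec.epsilon,
        },
        "model_data_hash": request.model.metadata.get("data_hash"),
        "gene": request.context.gene,
        "exon_number": request.context.exon_number,
    }
    return ScanResult(table=table, metadata=metadata)


def export_scan(result: ScanResult, path: str | Path, format: str = "tsv") -> None:
    """Write a scan result to TSV (canonical) or JSON.

    The TSV carries the run metadata in ``#``-prefixed header lines;
    undefined smoothed positions are exported as empty fields.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for key, value in result.metadata.items():
                fh.write(f"# {key}: {value}\n")
            result.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        payload = {
            "metadata": result.metadata,
            "windows": json.loads(
                result.table.to_json(orient="records", double_precision=10)
            ),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r} (expected tsv or json)")


def read_scan_tsv(path: str | Path) -> pd.DataFrame:
    """Read back the data rows of an exported scan TSV."""
    return pd.read_csv(path, sep="\t", comment="#")


def load_context_fasta(path: str | Path) -> TargetContext:
    """Load a target context from a three-record FASTA.

    Records may appear in any order when their ids contain ``upstream``,
    ``exon`` and ``downstream``; otherwise the three records are taken
    positionally as upstream intron, exon, downstream intron.
    """
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if len(seqs) != 3:
        raise ValueError(f"expected 3 FASTA records (upstream, exon, downstream), got {len(seqs)}")
    by_role: dict[str, str] = {}
    for rec in seqs:
        rid = rec.id.lower()
        for role in ("upstream", "downstream", "exon"):
            if role in rid and role not in by_role:
                by_role[role] = str(rec.seq)
                break
    if set(by_role) != {"upstream", "exon", "downstream"}:
        by_role = {
            "upstream": str(seqs[0].seq),
            "exon": str(seqs[1].seq),
            "downstream": str(seqs[2].seq),
        }
    return TargetContext(
        exon_seq=by_role["exon"],
        upstream_intron=by_role["upstream"],
        downstream_intron=by_role["downstream"],
    )


def plot_scan(result: ScanResult, path: str | Path) -> None:
    """Optional profile plot (requires matplotlib; headless-safe).

    Raw predictions are floored at 0 for display only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(9, 3.5))
    ax.plot(t["window_start"], np.maximum(t["predicted_efficacy"], 0.0),
            lw=1.2, label="predicted efficacy")
    ax.plot(t["window_start"], np.maximum(t["smoothed"], 0.0),
            ls="--", lw=1.2, label=f"{SMOOTHING_WINDOW}-base moving average")
    ax.set_xlabel("window start (exon coordinate)")
    ax.set_ylabel("relative skipping efficacy")
    ax.set_title(
        f"{result.metadata.get('chemistry')} {result.metadata.get('aso_length')}-mer scan"
    )
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
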