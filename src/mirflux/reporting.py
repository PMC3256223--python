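"""Figure/table surrogates and run bookkeeping.

Heatmaps render log2-ratio matrices with sub-threshold cells masked white
and a color scale symmetric around 0; dose curves are plotted on log-x
axes; rankings export as TSV with p-values in 3-significant-digit
scientific notation.  A :class:`RunManifest` captures config, seeds and
output checksums so a run can be re-verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .experiments import HeatmapResult

__all__ = ["render_heatmap", "render_dose_curves", "export_ranking", "RunManifest"]


def render_heatmap(h: HeatmapResult, path, title: str = "") -> None:
    """Render a log2-ratio heatmap; masked (|ratio| < threshold) cells are white."""
    data = h.ratios.to_numpy(dtype=float)
    masked = np.ma.masked_where(h.mask.to_numpy(), data)
    span = float(np.nanmax(np.abs(data))) if data.size else 1.0
    span = span or 1.0
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * data.shape[1] + 2),
                                    max(3, 0.3 * data.shape[0] + 2)))
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad("white")
    im = ax.imshow(masked, cmap=cmap, vmin=-span, vmax=span, aspect="auto")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels([str(c) for c in h.ratios.columns], rotation=90, fontsize=7)
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels([str(i) for i in h.ratios.index], fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 ratio vs control")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata=_no_date_metadata(path))
    plt.close(fig)


def render_dose_curves(table: pd.DataFrame, path, title: str = "",
                       ylabel: str = "steady state (nM)") -> None:
    """Plot steady-state readouts against dose (log-scaled x where possible)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = table.index.to_numpy(dtype=float)
    for col in table.columns:
        ax.plot(x, table[col].to_numpy(dtype=float), marker="o", label=str(col))
    if (x > 0).all():
        ax.set_xscale("log")
    ax.set_xlabel(table.index.name or "dose (nM)")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata=_no_date_metadata(path))
    plt.close(fig)


def _no_date_metadata(path) -> dict:
    # keep rendered files byte-reproducible
    if str(path).endswith(".svg"):
        return {"Date": None}
    return {}


def export_ranking(ranking: pd.DataFrame, path) -> None:
    """Write a ranking table as TSV with columns anti-miRNA, P-value.

    P-values are printed in scientific notation with 3 significant digits
    (round-trippable to that precision).
    """
    out = pd.DataFrame({
        "anti-miRNA": ranking["anti_mirna"],
        "P-value": [f"{p:.2e}" for p in ranking["p_value"]],
    })
    out.to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Bookkeeping for a pipeline run: config, seeds and output checksums."""

    config: dict = field(default_factory=dict)
    seed: int = 0
    fixture_checksum: str = ""
    software_version: str = ""
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def record(self, path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def verify(self) -> dict:
        """Re-hash every recorded output; returns {path: matches?}."""
        return {p: (Path(p).exists() and _sha256(Path(p)) == h)
                for p, h in self.outputs.items()}
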