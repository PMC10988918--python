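"""Back-gating: select cells in embedding space, view them on a marker pair.

A back-gate inverts the usual direction of gating: instead of drawing a
boundary on a marker scatter and looking at the selection in latent space,
cells are selected in the embedding (by geometry, by a metadata category such
as an annotated cluster, or as an explicit barcode list) and then highlighted
on a feature-pair scatter to see whether the population separates cleanly on
those two markers.

Membership in embedding space reuses the exact same geometric predicate as
forward gates (single source of truth). The density layer under the scatter
is a plain 2-D histogram over the data's bounding box — deterministic and
exactly count-conserving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .container import OmicsContainer
from .errors import FeatureNotFoundError, ValidationError
from .gates import Geometry, points_in_geometry

__all__ = [
    "BackGateSelection",
    "select_in_embedding",
    "select_by_metadata",
    "BackgateResult",
    "backgate_table",
    "density_grid",
]


@dataclass(frozen=True)
class BackGateSelection:
    """A resolved selection of cells and where it came from."""

    source: str  # "embedding_geometry" | "metadata_category" | "explicit_barcodes"
    detail: str
    resolved_barcodes: tuple[str, ...]

    @property
    def n_selected(self) -> int:
        return len(self.resolved_barcodes)


def select_in_embedding(
    container: OmicsContainer, embedding_name: str, geometry: Geometry
) -> BackGateSelection:
    """Cells whose embedding point (first two dimensions) lies in `geometry`."""
    if embedding_name not in container.embeddings:
        raise FeatureNotFoundError(
            f"embedding {embedding_name!r} not in container "
            f"(available: {sorted(container.embeddings)})"
        )
    emb = container.embeddings[embedding_name]
    if emb.shape[1] < 2:
        raise ValidationError(
            f"embedding {embedding_name!r} has {emb.shape[1]} dimension(s); need >= 2"
        )
    inside = points_in_geometry(emb[:, :2], geometry)
    barcodes = tuple(str(b) for b in container.barcodes[inside])
    if not barcodes:
        warnings.warn(
            f"embedding selection in {embedding_name!r} caught no cells",
            UserWarning,
            stacklevel=2,
        )
    return BackGateSelection(
        source="embedding_geometry",
        detail=f"{embedding_name}:{geometry.kind}",
        resolved_barcodes=barcodes,
    )


def select_by_metadata(
    container: OmicsContainer, column: str, value
) -> BackGateSelection:
    """Cells whose metadata `column` equals `value` (e.g. cluster == 'NK')."""
    if column not in container.cell_meta.columns:
        raise FeatureNotFoundError(
            f"metadata column {column!r} not in cell_meta "
            f"(available: {list(container.cell_meta.columns)})"
        )
    mask = (container.cell_meta[column].astype(str) == str(value)).to_numpy()
    barcodes = tuple(str(b) for b in container.barcodes[mask])
    if not barcodes:
        warnings.warn(
            f"metadata selection {column}={value!r} caught no cells",
            UserWarning,
            stacklevel=2,
        )
    return BackGateSelection(
        source="metadata_category",
        detail=f"{column}={value}",
        resolved_barcodes=barcodes,
    )


def select_explicit(container: OmicsContainer, barcodes) -> BackGateSelection:
    container.barcode_positions(barcodes)  # validates membership
    return BackGateSelection(
        source="explicit_barcodes",
        detail=f"{len(tuple(barcodes))} barcodes",
        resolved_barcodes=tuple(str(b) for b in barcodes),
    )


@dataclass
class BackgateResult:
    table: pd.DataFrame  # barcode-indexed: value_x, value_y, highlighted
    summary: dict


def backgate_table(
    container: OmicsContainer,
    selection: BackGateSelection,
    assay_x: str,
    feature_x: str,
    assay_y: str,
    feature_y: str,
    value_source: str = "auto",
) -> BackgateResult:
    """Per-cell feature values with a highlighted flag, plus group medians.

    The summary reports the highlighted count and the median of each feature
    within and outside the selection (NaN for an empty side).
    """
    xv = container.feature_values(assay_x, feature_x, source=value_source)
    yv = container.feature_values(assay_y, feature_y, source=value_source)
    sel = set(selection.resolved_barcodes)
    highlighted = np.fromiter(
        (str(b) in sel for b in container.barcodes), dtype=bool, count=container.n_cells
    )
    table = pd.DataFrame(
        {"value_x": xv, "value_y": yv, "highlighted": highlighted},
        index=container.barcodes,
    )

    def _median(v: np.ndarray) -> float:
        return float(np.median(v)) if v.size else float("nan")

    summary = {
        "n_highlighted": int(highlighted.sum()),
        "n_total": container.n_cells,
        "feature_x": f"{assay_x}:{feature_x}",
        "feature_y": f"{assay_y}:{feature_y}",
        "median_x_in": _median(xv[highlighted]),
        "median_x_out": _median(xv[~highlighted]),
        "median_y_in": _median(yv[highlighted]),
        "median_y_out": _median(yv[~highlighted]),
    }
    return BackgateResult(table=table, summary=summary)


def density_grid(
    values_x, values_y, bins: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram over the data's bounding box; the grid sums to n exactly.

    Returns (counts[bins, bins], x_edges, y_edges). This is the density layer
    drawn under back-gate scatters; smoothing, if wanted for display, is the
    plotting layer's business.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("values_x and values_y must be equal-length 1-D arrays")
    if x.size == 0:
        raise ValidationError("density_grid needs at least one point")
    if bins < 1:
        raise ValidationError("bins must be >= 1")
    # degenerate bounding boxes (single point / constant axis) need padding
    def _range(v):
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        return lo, hi

    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=[_range(x), _range(y)])
    return counts, xe, ye
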