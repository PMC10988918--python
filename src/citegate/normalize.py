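"""Normalization of antibody (ADT) and RNA count matrices.

Antibody-tag counts are compositional: each cell's counts compete for a
sequencing budget, so gating operates on centered log-ratio (CLR) values
rather than raw counts. Two margins are supported:

* ``across_cells`` (default): each ADT feature is centered over all cells —
  the common practice for antibody panels, robust to per-cell composition.
* ``within_cell``: each cell's ADT vector is centered over its features —
  the textbook compositional-data transform.

and two variants:

* ``log1p_centered`` (default): ``y_i = ln(1 + x_i) - mean_j ln(1 + x_j)``.
* ``pure_log_ratio``: ``y_i = ln(x_i + c) - mean_j ln(x_j + c)`` with a
  configurable pseudocount ``c``.

Both center their margin vectors to zero mean exactly; an all-zero margin
vector maps to zeros, never NaN. RNA normalization is a standard per-cell
library-size log transform and is optional — QC metrics use raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import scipy.sparse as sp

from .container import OmicsContainer
from .errors import ValidationError

__all__ = [
    "NormalizationConfig",
    "clr_normalize",
    "log_normalize_rna",
    "ensure_adt_normalized",
]

_METHODS = {"clr", "none", "external"}
_MARGINS = {"within_cell", "across_cells"}
_VARIANTS = {"pure_log_ratio", "log1p_centered"}


@dataclass(frozen=True)
class NormalizationConfig:
    method: str = "clr"
    margin: str = "across_cells"
    pseudocount: float = 1.0
    clr_variant: str = "log1p_centered"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValidationError(f"unknown normalization method {self.method!r}")
        if self.margin not in _MARGINS:
            raise ValidationError(f"unknown CLR margin {self.margin!r}")
        if self.clr_variant not in _VARIANTS:
            raise ValidationError(f"unknown CLR variant {self.clr_variant!r}")
        if not self.pseudocount > 0:
            raise ValidationError("pseudocount must be > 0")

    def record(self) -> dict:
        """JSON-safe record stored in gate audit trails."""
        return asdict(self)


def _dense(raw) -> np.ndarray:
    x = raw.toarray() if sp.issparse(raw) else np.asarray(raw)
    return np.asarray(x, dtype=np.float64)


def clr_normalize(raw, config: NormalizationConfig = NormalizationConfig()) -> np.ndarray:
    """Centered log-ratio transform of a non-negative counts matrix.

    Returns a dense matrix of the same shape whose margin vectors (rows for
    ``within_cell``, columns for ``across_cells``) have exactly zero mean.
    """
    x = _dense(raw)
    if x.size and x.min() < 0:
        raise ValidationError("CLR input must be non-negative")
    if config.clr_variant == "log1p_centered":
        logx = np.log1p(x)
    else:
        logx = np.log(x + config.pseudocount)
    axis = 1 if config.margin == "within_cell" else 0
    return logx - logx.mean(axis=axis, keepdims=True)


def log_normalize_rna(raw, scale_factor: float = 10_000.0) -> np.ndarray:
    """Per-cell library-size log normalization: ln(1 + s * x / total_cell).

    Cells with zero total counts come out as all-zero rows (with a warning).
    """
    if not scale_factor > 0:
        raise ValidationError("scale_factor must be > 0")
    x = _dense(raw)
    if x.size and x.min() < 0:
        raise ValidationError("RNA normalization input must be non-negative")
    totals = x.sum(axis=1, keepdims=True)
    zero = totals.ravel() == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero RNA counts normalized to zeros",
            UserWarning,
            stacklevel=2,
        )
    safe = np.where(totals == 0, 1.0, totals)
    return np.log1p(scale_factor * x / safe)


def ensure_adt_normalized(
    container: OmicsContainer,
    config: NormalizationConfig = NormalizationConfig(),
) -> OmicsContainer:
    """Fill the ADT normalized slot in place if absent; return the container.

    method="none" refuses (gating requires normalized ADT values unless raw
    gating is requested explicitly); method="external" requires the slot to
    have been supplied upstream.
    """
    if "ADT" not in container.assays:
        raise ValidationError("container has no ADT assay; cannot gate")
    adt = container.assays["ADT"]
    if adt.normalized is not None:
        return container
    if config.method == "clr":
        adt.normalized = clr_normalize(adt.raw, config)
        adt.normalization = config.record()
        return container
    if config.method == "external":
        raise ValidationError(
            "normalization method 'external' but the ADT normalized slot is empty"
        )
    raise ValidationError(
        "ADT assay is not normalized and normalization method is 'none'"
    )
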