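"""Multimodal single-cell container used throughout the gating workflow.

An :class:`OmicsContainer` holds one or more assays (e.g. ``"RNA"`` gene
expression and ``"ADT"`` antibody capture) over a shared, ordered set of cell
barcodes, plus any number of 2-D+ embeddings (UMAP/PCA/...) and a per-cell
metadata table. Cell barcodes are the primary key everywhere: gates, back-gate
selections and exports all speak barcodes, never positional indices.

Raw counts are stored sparse (CSR, cells as rows); normalized matrices are
dense. Gating reads the ADT ``normalized`` slot — a container without it is
loadable but not gateable until normalization is applied.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FeatureNotFoundError, ValidationError

__all__ = ["Assay", "OmicsContainer"]


@dataclass
class Assay:
    """One modality: cells x features raw counts plus optional normalized matrix."""

    feature_names: pd.Index
    raw: sp.csr_matrix
    normalized: np.ndarray | None = None
    #: record of how `normalized` was produced (method/margin/variant), if known
    normalization: dict | None = None

    def __post_init__(self) -> None:
        self.feature_names = pd.Index(self.feature_names)
        if not sp.issparse(self.raw):
            self.raw = sp.csr_matrix(np.asarray(self.raw))
        else:
            self.raw = self.raw.tocsr()
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def validate(self, n_cells: int, name: str = "?") -> None:
        if self.feature_names.has_duplicates:
            dup = self.feature_names[self.feature_names.duplicated()][0]
            raise ValidationError(f"assay {name!r}: duplicate feature name {dup!r}")
        if self.raw.shape != (n_cells, self.n_features):
            raise ValidationError(
                f"assay {name!r}: raw shape {self.raw.shape} != "
                f"({n_cells}, {self.n_features})"
            )
        if self.raw.nnz and self.raw.data.min() < 0:
            raise ValidationError(f"assay {name!r}: raw counts must be >= 0")
        if self.normalized is not None and self.normalized.shape != self.raw.shape:
            raise ValidationError(
                f"assay {name!r}: normalized shape {self.normalized.shape} "
                f"!= raw shape {self.raw.shape}"
            )


@dataclass
class OmicsContainer:
    barcodes: pd.Index
    assays: dict[str, Assay] = field(default_factory=dict)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.barcodes = pd.Index(self.barcodes, dtype=object)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.barcodes)
        self.embeddings = {k: np.asarray(v, dtype=float) for k, v in self.embeddings.items()}
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.barcodes)
        if n == 0:
            raise ValidationError("container must hold at least one cell")
        if self.barcodes.has_duplicates:
            dup = self.barcodes[self.barcodes.duplicated()][0]
            raise ValidationError(f"duplicate cell barcode: {dup!r}")
        for name, assay in self.assays.items():
            assay.validate(n, name)
        for name, emb in self.embeddings.items():
            if emb.ndim != 2 or emb.shape[0] != n:
                raise ValidationError(
                    f"embedding {name!r}: shape {emb.shape} incompatible with {n} cells"
                )
        if len(self.cell_meta) != n:
            raise ValidationError(
                f"cell_meta has {len(self.cell_meta)} rows for {n} cells"
            )

    # -- basic views --------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def gateable(self) -> bool:
        """True when an ADT assay with a normalized matrix is present."""
        adt = self.assays.get("ADT")
        return adt is not None and adt.normalized is not None

    @property
    def has_adt(self) -> bool:
        return "ADT" in self.assays

    def barcode_positions(self, barcodes) -> np.ndarray:
        """Integer row positions of `barcodes`, erroring on unknown ones."""
        idx = self.barcodes.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            bad = pd.Index(barcodes)[idx < 0][0]
            raise ValidationError(f"barcode not in container: {bad!r}")
        return idx

    def feature_values(
        self, assay: str, feature: str, barcodes=None, source: str = "auto"
    ) -> np.ndarray:
        """Per-cell values of one feature.

        source: "normalized", "raw", or "auto" (normalized when present for
        the assay, raw otherwise — except ADT, where "auto" requires the
        normalized slot because gating is defined on normalized ADT values).
        """
        if assay not in self.assays:
            raise FeatureNotFoundError(
                f"assay {assay!r} not in container (have: {sorted(self.assays)})"
            )
        a = self.assays[assay]
        loc = a.feature_names.get_indexer([feature])[0]
        if loc < 0:
            raise FeatureNotFoundError(f"feature {feature!r} not in assay {assay!r}")
        if source == "auto":
            if a.normalized is not None:
                source = "normalized"
            elif assay == "ADT":
                raise ValidationError(
                    "ADT assay has no normalized matrix; run CLR normalization "
                    "first or request source='raw' explicitly"
                )
            else:
                source = "raw"
        if source == "normalized":
            if a.normalized is None:
                raise ValidationError(f"assay {assay!r} has no normalized matrix")
            col = a.normalized[:, loc]
        elif source == "raw":
            col = np.asarray(a.raw[:, [loc]].todense()).ravel()
        else:
            raise ValidationError(f"unknown value source {source!r}")
        if barcodes is not None:
            col = col[self.barcode_positions(barcodes)]
        return np.asarray(col, dtype=float)

    def resolved_source(self, assay: str) -> str:
        """The value source 'auto' resolves to for this assay."""
        a = self.assays[assay]
        return "normalized" if a.normalized is not None else "raw"

    # -- subsetting ---------------------------------------------------------
    def subset(self, barcodes) -> "OmicsContainer":
        """New container restricted to `barcodes`, container order preserved."""
        pos = np.sort(self.barcode_positions(barcodes))
        assays = {
            name: Assay(
                feature_names=a.feature_names,
                raw=a.raw[pos],
                normalized=None if a.normalized is None else a.normalized[pos],
                normalization=a.normalization,
            )
            for name, a in self.assays.items()
        }
        return OmicsContainer(
            barcodes=self.barcodes[pos],
            assays=assays,
            embeddings={k: v[pos] for k, v in self.embeddings.items()},
            cell_meta=self.cell_meta.iloc[pos].copy(),
        )

    # -- provenance ---------------------------------------------------------
    def fingerprint(self) -> str:
        """Stable hex digest over barcodes and assay shapes/feature names.

        Used to tie gate audit files to the container they were computed on.
        Raw count values are not hashed (cheapness over tamper-evidence).
        """
        h = hashlib.sha256()
        for b in self.barcodes:
            h.update(str(b).encode())
            h.update(b"\0")
        for name in sorted(self.assays):
            a = self.assays[name]
            h.update(name.encode())
            h.update(str(a.raw.shape).encode())
            for f in a.feature_names:
                h.update(str(f).encode())
                h.update(b"\1")
        return h.hexdigest()[:16]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        assays = ", ".join(f"{k}({v.n_features})" for k, v in self.assays.items())
        return (
            f"OmicsContainer({self.n_cells} cells; assays: {assays or 'none'}; "
            f"embeddings: {sorted(self.embeddings) or 'none'})"
        )


def warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=3)
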