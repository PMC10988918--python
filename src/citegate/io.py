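"""Reading and writing multimodal single-cell data.

Supported inputs:

* 10x-style MTX triplet directory (``matrix.mtx[.gz]``, ``barcodes.tsv[.gz]``,
  ``features.tsv[.gz]``) whose features file carries a feature-type column;
  "Gene Expression" rows become the RNA assay, "Antibody Capture" the ADT assay.
* An annotated-matrix container file (``.h5ad``) — either one written by
  :func:`write_container` or a generic AnnData whose ``var`` has a
  feature-type/modality column.
* Plain CSV matrices (cells x features, first column = barcode) via
  :func:`read_csv_assays`.

Native R serializations (RDS / Seurat objects) are deliberately not parsed.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .container import Assay, OmicsContainer
from .errors import FormatError, ValidationError

__all__ = [
    "read_10x_mtx",
    "read_container",
    "write_container",
    "read_csv_assays",
    "downsample",
    "write_barcodes",
    "read_barcodes",
]

_CONTAINER_VERSION = 1
# modality labels mapped onto assay names
_MODALITY_MAP = {
    "Gene Expression": "RNA",
    "Antibody Capture": "ADT",
    "RNA": "RNA",
    "ADT": "ADT",
}


def _find_member(path: Path, stem: str) -> Path:
    for cand in (path / stem, path / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FormatError(f"10x directory {path} is missing member file {stem}[.gz]")


def read_10x_mtx(path) -> OmicsContainer:
    """Read a 10x MTX triplet directory into an :class:`OmicsContainer`.

    Counts are preserved exactly and barcode order follows the barcodes file.
    The features file must have a third (feature-type) column so antibody
    capture rows can be routed to the ADT assay.
    """
    from scipy.io import mmread

    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"not a directory: {path}")
    matrix_file = _find_member(path, "matrix.mtx")
    barcodes_file = _find_member(path, "barcodes.tsv")
    features_file = _find_member(path, "features.tsv")

    feats = pd.read_csv(features_file, sep="\t", header=None)
    if feats.shape[1] < 3:
        raise FormatError(
            f"{features_file} has {feats.shape[1]} columns; a feature-type "
            "column (3rd) is required to distinguish Gene Expression from "
            "Antibody Capture"
        )
    bcs = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str)
    if bcs.duplicated().any():
        dup = bcs[bcs.duplicated()].iloc[0]
        raise ValidationError(f"duplicate barcode in {barcodes_file}: {dup!r}")

    opener = gzip.open if matrix_file.suffix == ".gz" else open
    try:
        with opener(matrix_file, "rb") as fh:
            mat = mmread(fh)
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file {matrix_file}: {exc}") from exc
    X = sp.csr_matrix(mat).T  # MTX is features x cells; store cells as rows
    if X.shape != (len(bcs), len(feats)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(feats)} features "
            f"x {len(bcs)} barcodes"
        )

    names = feats[1].astype(str).to_numpy()
    assay_of = np.array([_MODALITY_MAP.get(t, "OTHER") for t in feats[2].astype(str)])
    assays: dict[str, Assay] = {}
    for assay_name in pd.unique(assay_of):
        mask = assay_of == assay_name
        assays[str(assay_name)] = Assay(
            feature_names=pd.Index(names[mask]), raw=X[:, mask]
        )
    return OmicsContainer(barcodes=pd.Index(bcs), assays=assays)


def read_csv_assays(paths: dict[str, str]) -> OmicsContainer:
    """Build a container from CSV matrices, one per assay.

    Each CSV is cells x features with a header row of feature names and the
    first column holding cell barcodes. All files must agree on barcodes and
    their order.
    """
    if not paths:
        raise ValidationError("at least one assay CSV is required")
    assays: dict[str, Assay] = {}
    barcodes: pd.Index | None = None
    for assay_name, p in paths.items():
        df = pd.read_csv(p, index_col=0)
        if barcodes is None:
            barcodes = pd.Index(df.index.astype(str))
        elif not barcodes.equals(pd.Index(df.index.astype(str))):
            raise ValidationError(
                f"assay {assay_name!r} CSV barcodes differ from the first assay's"
            )
        assays[assay_name] = Assay(
            feature_names=pd.Index(df.columns.astype(str)),
            raw=sp.csr_matrix(df.to_numpy()),
        )
    return OmicsContainer(barcodes=barcodes, assays=assays)


# ---------------------------------------------------------------------------
# container (h5ad) round-trip
# ---------------------------------------------------------------------------

def write_container(container: OmicsContainer, path) -> None:
    """Serialize a container to ``.h5ad`` losslessly.

    Assays are concatenated along the feature axis with a modality column;
    normalized matrices go into a dense layer (NaN where an assay has none).
    """
    container.validate()
    names, assay_col, mats = [], [], []
    norm_blocks = []
    any_norm = False
    for aname, a in container.assays.items():
        names.extend(str(f) for f in a.feature_names)
        assay_col.extend([aname] * a.n_features)
        mats.append(a.raw)
        if a.normalized is not None:
            any_norm = True
            norm_blocks.append(np.asarray(a.normalized, dtype=np.float64))
        else:
            norm_blocks.append(
                np.full((container.n_cells, a.n_features), np.nan, dtype=np.float64)
            )
    X = sp.hstack(mats, format="csr") if mats else sp.csr_matrix(
        (container.n_cells, 0)
    )
    var = pd.DataFrame(
        {"feature_name": names, "assay": assay_col},
        index=pd.Index([f"{a}:{n}" for a, n in zip(assay_col, names)], name="key"),
    )
    adata = ad.AnnData(X=X, var=var, obs=container.cell_meta.copy())
    adata.obs_names = [str(b) for b in container.barcodes]
    if any_norm:
        adata.layers["normalized"] = np.concatenate(norm_blocks, axis=1)
    for ename, emb in container.embeddings.items():
        adata.obsm[ename] = emb
    adata.uns["citegate_container_version"] = _CONTAINER_VERSION
    adata.uns["normalization"] = {
        aname: dict(a.normalization)
        for aname, a in container.assays.items()
        if a.normalization
    }
    adata.write_h5ad(Path(path))


def read_container(path) -> OmicsContainer:
    """Read a serialized annotated-matrix container file.

    Understands both the dialect written by :func:`write_container` and a
    generic AnnData whose ``var`` carries a ``feature_types`` modality column
    ("Antibody Capture"/"ADT" rows become the ADT assay). A container without
    an ADT-like modality is returned with a warning; it is not gateable.
    """
    path = Path(path)
    try:
        adata = ad.read_h5ad(path)
    except OSError as exc:
        raise FormatError(f"cannot read container file {path}: {exc}") from exc

    var = adata.var
    if "assay" in var.columns:
        assay_col = var["assay"].astype(str)
        name_col = var.get("feature_name", pd.Series(var.index, index=var.index)).astype(str)
    elif "feature_types" in var.columns:
        assay_col = var["feature_types"].astype(str).map(
            lambda m: _MODALITY_MAP.get(m, "OTHER")
        )
        name_col = pd.Series(var.index, index=var.index).astype(str)
    else:
        assay_col = pd.Series("RNA", index=var.index)
        name_col = pd.Series(var.index, index=var.index).astype(str)

    X = sp.csr_matrix(adata.X)
    norm_layer = adata.layers.get("normalized")
    norm_records = dict(adata.uns.get("normalization", {}))

    assays: dict[str, Assay] = {}
    for aname in pd.unique(assay_col):
        mask = (assay_col == aname).to_numpy()
        normalized = None
        if norm_layer is not None:
            block = np.asarray(norm_layer)[:, mask]
            if not np.isnan(block).all():
                normalized = block
        assays[str(aname)] = Assay(
            feature_names=pd.Index(name_col[mask]),
            raw=X[:, mask],
            normalized=normalized,
            normalization=norm_records.get(str(aname)) or None,
        )
    if "ADT" not in assays:
        warnings.warn(
            f"{path.name}: no ADT-like modality found; container is not gateable",
            UserWarning,
            stacklevel=2,
        )
    embeddings = {str(k): np.asarray(v) for k, v in adata.obsm.items()}
    # common AnnData convention: obsm["X_umap"] -> embedding "UMAP"
    embeddings = {
        (k[2:].upper() if k.startswith("X_") else k): v for k, v in embeddings.items()
    }
    return OmicsContainer(
        barcodes=pd.Index(adata.obs_names.astype(str)),
        assays=assays,
        embeddings=embeddings,
        cell_meta=adata.obs.copy(),
    )


# ---------------------------------------------------------------------------
# subsetting and barcode lists
# ---------------------------------------------------------------------------

def downsample(container: OmicsContainer, n: int, seed: int) -> OmicsContainer:
    """Uniform sample of `n` cells without replacement, seeded and reproducible.

    Selected cells keep their container order.
    """
    if not 0 < n <= container.n_cells:
        raise ValidationError(
            f"downsample size {n} out of range (container has {container.n_cells} cells)"
        )
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(container.n_cells, size=n, replace=False))
    return container.subset(container.barcodes[pos])


def write_barcodes(barcodes, path) -> None:
    """Write one barcode per line (newline-terminated), gzip by extension."""
    barcodes = list(barcodes)
    if not barcodes:
        warnings.warn(f"writing empty barcode list to {path}", UserWarning, stacklevel=2)
    path = Path(path)
    text = "".join(f"{b}\n" for b in barcodes)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


def read_barcodes(path) -> list[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]
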