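"""File formats: 10x MTX triplets (with spliced/unspliced layers), GMT, BED.

Count matrices travel as MatrixMarket coordinate-integer triplets with
barcodes.tsv and features.tsv companions (genes x cells on disk, the 10x
convention); optional spliced.mtx / unspliced.mtx files carry the velocity
layers.  Gzipped triplets are accepted transparently.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, List

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(path: Path, stem: str) -> Path:
    for cand in (path / stem, path / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing required file {stem}(.gz) in {path}")


def read_mtx_layers(path: str | Path) -> ad.AnnData:
    """Read a 10x MTX triplet directory, plus optional velocity layers.

    Expects matrix.mtx(.gz), barcodes.tsv(.gz), features.tsv(.gz); reads
    spliced.mtx / unspliced.mtx as layers when present, checking shapes.
    Returns cells x genes AnnData with integer counts.
    """
    path = Path(path)
    with _open_maybe_gz(_find(path, "matrix.mtx")) as fh:
        X = sp.csr_matrix(mmread(fh)).T  # disk is genes x cells
    barcodes = pd.read_csv(_find(path, "barcodes.tsv"), header=None, sep="\t")[0]
    feat = pd.read_csv(_find(path, "features.tsv"), header=None, sep="\t")
    if X.shape != (len(barcodes), len(feat)):
        raise ValueError(f"matrix shape {X.shape} does not match "
                         f"{len(barcodes)} barcodes x {len(feat)} features")
    var = pd.DataFrame(index=pd.Index(feat[0], name="gene"))
    if feat.shape[1] > 1:
        var["symbol"] = feat[1].to_numpy()
    adata = ad.AnnData(X=X.astype(np.int64),
                       obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
                       var=var)
    for layer in ("spliced", "unspliced"):
        try:
            f = _find(path, f"{layer}.mtx")
        except FileNotFoundError:
            continue
        with _open_maybe_gz(f) as fh:
            L = sp.csr_matrix(mmread(fh)).T
        if L.shape != adata.shape:
            raise ValueError(f"layer {layer} shape {L.shape} mismatches matrix {adata.shape}")
        adata.layers[layer] = L.astype(np.int64)
    return adata


def write_mtx_layers(adata: ad.AnnData, path: str | Path, gzip_files: bool = False) -> None:
    """Write a 10x MTX triplet (genes x cells on disk) plus layers."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip_files else ""

    def write_mtx(mat, name):
        target = path / f"{name}.mtx{suffix}"
        with _open_maybe_gz(target, "wb") as fh:
            mmwrite(fh, sp.coo_matrix(mat.T), field="integer")

    write_mtx(sp.csr_matrix(adata.X).astype(np.int64), "matrix")
    for layer in ("spliced", "unspliced"):
        if layer in adata.layers:
            write_mtx(sp.csr_matrix(adata.layers[layer]).astype(np.int64), layer)
    with _open_maybe_gz(path / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    with _open_maybe_gz(path / f"features.tsv{suffix}", "wt") as fh:
        for g in adata.var_names:
            fh.write(f"{g}\t{g}\tGene Expression\n")


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets = {}
    with _open_maybe_gz(Path(path)) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Dict[str, List[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "."] + list(genes)) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Peak intervals from BED/narrowPeak: half-open, 0-based coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = df.iloc[:, :3].copy()
    out.columns = ["chromosome", "start", "end"]
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[["chromosome", "start", "end"]].to_csv(path, sep="\t", header=False,
                                                 index=False)
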