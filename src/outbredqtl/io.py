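"""File formats: TSV for tables, HDF5 for tensors/LOD matrices, JSON for
ground truth and manifests.

Every tabular output carries a header comment with the package version, the
master seed and a config hash, so a run can be traced from its artifacts.
Readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .data import AlleleProbabilityTensor, ExpressionPanel

HEADER_KEY = "outbredqtl"


def _header(seed: int | None, config_hash: str | None) -> str:
    parts = [f"# {HEADER_KEY} v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts) + "\n"


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config snapshot."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_tsv(
    df: pd.DataFrame,
    path,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# Genotypes


def write_alleleprobs(
    geno: AlleleProbabilityTensor, path, seed: int | None = None
) -> None:
    """HDF5 layout: probs (n x M x 8), founders, markers, individuals."""
    with h5py.File(path, "w") as fh:
        fh.attrs["version"] = __version__
        if seed is not None:
            fh.attrs["seed"] = seed
        fh.create_dataset("probs", data=geno.probs)
        fh.create_dataset(
            "founders", data=np.array(geno.founders, dtype="S")
        )
        fh.create_dataset(
            "individuals", data=np.array(geno.individuals, dtype="S")
        )
        fh.create_dataset("markers", data=geno.markers.index.to_numpy(dtype="S"))


def read_alleleprobs(path, markers: pd.DataFrame) -> AlleleProbabilityTensor:
    with h5py.File(path, "r") as fh:
        probs = fh["probs"][()]
        individuals = [s.decode() for s in fh["individuals"][()]]
        founders = tuple(s.decode() for s in fh["founders"][()])
        names = [s.decode() for s in fh["markers"][()]]
    if list(markers.index) != names:
        raise ValueError("marker map does not match the stored marker order")
    return AlleleProbabilityTensor(probs, individuals, markers, founders)


def write_markers(markers: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    write_tsv(markers, path, seed, cfg_hash)


def read_markers(path) -> pd.DataFrame:
    df = read_tsv(path)
    df.index.name = "marker"
    df["chrom"] = df["chrom"].astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated marker ids: {dups[:5]}")
    if df["pos_mb"].isna().any():
        raise ValueError("NaN marker positions")
    return df


# ---------------------------------------------------------------------------
# Expression panel


def write_panel(
    panel: ExpressionPanel, outdir, seed=None, cfg_hash=None
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotations": outdir / "feature_annotations.tsv",
        "covariates": outdir / "covariates.tsv",
    }
    write_tsv(panel.values, paths["expression"], seed, cfg_hash)
    write_tsv(panel.annotations, paths["annotations"], seed, cfg_hash)
    write_tsv(panel.covariates, paths["covariates"], seed, cfg_hash)
    return paths


def read_panel(expression_path, annotations_path, covariates_path) -> ExpressionPanel:
    values = read_tsv(expression_path)
    ann = read_tsv(annotations_path)
    ann["chrom"] = ann["chrom"].astype(str)
    cov = read_tsv(covariates_path)
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].tolist()
        raise ValueError(f"duplicated feature ids: {dups[:5]}")
    if cov.index.duplicated().any():
        dups = cov.index[cov.index.duplicated()].tolist()
        raise ValueError(f"duplicated individual ids: {dups[:5]}")
    if "diet" not in cov.columns:
        raise ValueError("covariate table lacks a 'diet' column")
    missing = [i for i in values.columns if i not in cov.index]
    if missing:
        raise ValueError(f"individuals absent from covariates: {missing[:5]}")
    cov = cov.loc[values.columns]
    return ExpressionPanel(values, ann, cov)


def read_inputs(
    markers_path, probs_path, expression_path, annotations_path, covariates_path
) -> tuple[AlleleProbabilityTensor, ExpressionPanel]:
    """Load and align the full input layout on shared individuals."""
    from .data import align_to_individuals

    markers = read_markers(markers_path)
    geno = read_alleleprobs(probs_path, markers)
    panel = read_panel(expression_path, annotations_path, covariates_path)
    return align_to_individuals(geno, panel)


# ---------------------------------------------------------------------------
# Scan results


def write_lod(lod: pd.DataFrame, path, model: str, seed=None) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["version"] = __version__
        fh.attrs["model"] = model
        if seed is not None:
            fh.attrs["seed"] = seed
        fh.create_dataset("lod", data=lod.to_numpy())
        fh.create_dataset("markers", data=lod.index.to_numpy(dtype="S"))
        fh.create_dataset("phenotypes", data=lod.columns.to_numpy(dtype="S"))


def read_lod(path) -> tuple[pd.DataFrame, str]:
    with h5py.File(path, "r") as fh:
        lod = fh["lod"][()]
        markers = [s.decode() for s in fh["markers"][()]]
        phenos = [s.decode() for s in fh["phenotypes"][()]]
        model = fh.attrs.get("model", "additive")
    return pd.DataFrame(lod, index=markers, columns=phenos), str(model)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
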