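"""HDF5 containers and text import/export.

One HDF5 file per artifact kind: binned tracks, normalized contact maps,
window datasets and trained models.  Text formats follow the field's
conventions: chrom.sizes (two-column), BED3+ interval files, tabular track
dumps and BEDGraph state tracks.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .genome_tracks import FactorTrackSet, GenomeBins
from .hic_maps import NormalizedContactMap, RawContactMap
from .neural_models import DenseLayer, DenseStackParams, FilterParams, ForwardModel

__all__ = [
    "read_bed",
    "save_tracks",
    "load_tracks",
    "save_contact_map",
    "load_contact_map",
    "save_forward_model",
    "load_forward_model",
    "save_dense_stack",
    "load_dense_stack",
    "write_state_bedgraph",
    "tracks_to_table",
]

FORMAT_VERSION = 1


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    """Read a BED3+ file, keeping as many of the given columns as present."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    table.columns = list(names[: table.shape[1]]) + [
        f"col{i}" for i in range(len(names), table.shape[1])
    ]
    return table


def _write_bins(grp: h5py.Group, bins: GenomeBins) -> None:
    grp.attrs["bin_size"] = bins.bin_size
    grp.create_dataset("chrom_names", data=np.array(bins.chrom_names, dtype="S"))
    grp.create_dataset("chrom_lengths", data=np.array(bins.chrom_lengths))


def _read_bins(grp: h5py.Group) -> GenomeBins:
    return GenomeBins(
        chrom_names=tuple(n.decode() for n in grp["chrom_names"][:]),
        chrom_lengths=tuple(int(x) for x in grp["chrom_lengths"][:]),
        bin_size=int(grp.attrs["bin_size"]),
    )


def save_tracks(path, tracks: FactorTrackSet, bins: GenomeBins) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("values", data=tracks.values)
        f.create_dataset("factor_names", data=np.array(tracks.factor_names, dtype="S"))
        _write_bins(f.create_group("bins"), bins)


def load_tracks(path) -> tuple[FactorTrackSet, GenomeBins]:
    with h5py.File(path, "r") as f:
        tracks = FactorTrackSet(
            factor_names=[n.decode() for n in f["factor_names"][:]],
            values=f["values"][:],
        )
        bins = _read_bins(f["bins"])
    return tracks, bins


def save_contact_map(path, cmap) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["normalized"] = isinstance(cmap, NormalizedContactMap)
        for name in cmap.chrom_names:
            g = f.create_group(f"chrom/{name}")
            g.create_dataset("matrix", data=cmap.matrices[name])
            g.create_dataset("mask", data=cmap.masks[name])


def load_contact_map(path):
    with h5py.File(path, "r") as f:
        names = list(f["chrom"])
        mats = {n: f[f"chrom/{n}/matrix"][:] for n in names}
        masks = {n: f[f"chrom/{n}/mask"][:].astype(bool) for n in names}
        cls = NormalizedContactMap if f.attrs.get("normalized") else RawContactMap
        if cls is NormalizedContactMap:
            return NormalizedContactMap(chrom_names=names, matrices=mats, masks=masks)
        return RawContactMap(chrom_names=names, matrices=mats, masks=masks)


def save_dense_stack(path_or_group, stack: DenseStackParams) -> None:
    if isinstance(path_or_group, (h5py.File, h5py.Group)):
        _write_stack(path_or_group, stack)
    else:
        with h5py.File(path_or_group, "w") as f:
            f.attrs["format_version"] = FORMAT_VERSION
            _write_stack(f, stack)


def _write_stack(grp, stack: DenseStackParams) -> None:
    grp.attrs["n_layers"] = len(stack.layers)
    for li, layer in enumerate(stack.layers):
        g = grp.create_group(f"layer{li}")
        g.create_dataset("W", data=layer.W)
        g.create_dataset("b", data=layer.b)
        g.attrs["activation"] = layer.activation


def _read_stack(grp) -> DenseStackParams:
    layers = []
    for li in range(int(grp.attrs["n_layers"])):
        g = grp[f"layer{li}"]
        layers.append(
            DenseLayer(W=g["W"][:], b=g["b"][:], activation=g.attrs["activation"])
        )
    return DenseStackParams(layers)


def load_dense_stack(path) -> DenseStackParams:
    with h5py.File(path, "r") as f:
        return _read_stack(f)


def save_forward_model(path, model: ForwardModel, train_config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["w"] = model.w
        f.create_dataset("filter/W0", data=model.filter.W0)
        f.attrs["beta0"] = model.filter.beta0
        _write_stack(f.create_group("stack"), model.stack)
        if train_config:
            g = f.create_group("train_config")
            for k, v in train_config.items():
                g.attrs[k] = v


def load_forward_model(path) -> ForwardModel:
    with h5py.File(path, "r") as f:
        filt = FilterParams(W0=f["filter/W0"][:], beta0=float(f.attrs["beta0"]))
        stack = _read_stack(f["stack"])
        return ForwardModel(filter=filt, stack=stack, w=int(f.attrs["w"]))


def tracks_to_table(tracks: FactorTrackSet, bins: GenomeBins) -> pd.DataFrame:
    """Tabular dump: bin coordinates plus one column per factor."""
    table = bins.bin_table()
    for name, row in zip(tracks.factor_names, tracks.values):
        table[name] = row
    return table


def write_state_bedgraph(path, values: np.ndarray, bins: GenomeBins) -> None:
    """BEDGraph export of a per-bin state track (NaN bins skipped)."""
    table = bins.bin_table()
    table["value"] = np.asarray(values, dtype=float)
    table = table[np.isfinite(table["value"])]
    table.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
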