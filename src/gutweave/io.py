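"""Readers and writers for the pipeline's plain-text and image formats.

Tabular data travels as TSV (taxa/genes as rows, samples as columns, header
row plus a row-name column).  Annotations are two-column gene<TAB>GO:ID
files or a minimal GAF 2.x subset (columns 2 and 5).  Trees are newick.
Label masks are single-channel 16-bit PNG or TIFF with a JSON legend; ROIs
are JSON vertex lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_table(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_count_table(counts_path, metadata_path):
    from .containers import CountTable

    return CountTable(read_table(counts_path), read_metadata(metadata_path))


def read_annotation(path) -> dict:
    """gene<TAB>GO:ID pairs (one per line, optional header) → term → genes."""
    ann: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or parts[0].lower() in ("gene", "gene_id"):
                continue
            gene, term = parts[0], parts[1]
            ann.setdefault(term, set()).add(gene)
    return {t: sorted(g) for t, g in ann.items()}


def read_gaf(path) -> dict:
    """Minimal GAF 2.x: DB Object Symbol (col 2) and GO ID (col 5)."""
    ann: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            ann.setdefault(parts[4], set()).add(parts[1])
    return {t: sorted(g) for t, g in ann.items()}


def write_annotation(ann: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for term in sorted(ann):
            for gene in sorted(ann[term]):
                fh.write(f"{gene}\t{term}\n")


def read_tree(path):
    """Newick file → skbio TreeNode."""
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def write_tree(newick: str, path) -> None:
    Path(path).write_text(newick if newick.endswith("\n") else newick + "\n")


def write_label_mask(mask: np.ndarray, legend: dict, path) -> None:
    """16-bit single-channel PNG/TIFF plus sibling .legend.json."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("labels must fit in uint16")
    arr = arr.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)
    legend_path = path.with_suffix(path.suffix + ".legend.json")
    legend_path.write_text(json.dumps({str(k): v for k, v in legend.items()}, indent=1))


def read_label_mask(path, legend_path=None):
    """Returns a :class:`gutweave.histology.LabelMask`."""
    from .histology import LabelMask

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path), dtype=np.int64)
    if legend_path is None:
        legend_path = path.with_suffix(path.suffix + ".legend.json")
    raw = json.loads(Path(legend_path).read_text())
    legend = {}
    pixel_size = 1.0
    for k, v in raw.items():
        if k == "pixel_size_um":
            pixel_size = float(v)
        else:
            legend[int(k)] = v
    return LabelMask(np.asarray(arr, dtype=np.int64), legend, pixel_size)


def write_fluor_image(image: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_fluor_image(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def write_roi(vertices, path) -> None:
    Path(path).write_text(json.dumps({"vertices": [list(map(float, v)) for v in vertices]}))


def read_roi(path):
    data = json.loads(Path(path).read_text())
    return [tuple(v) for v in data["vertices"]]
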