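"""Node-label table for the 90-region cerebral parcellation.

The analysis operates on 90 regions of interest (45 per hemisphere) from the
Automated Anatomical Labeling atlas.  Odd indices are left-hemisphere, even
indices right-hemisphere regions; abbreviations carry an ``.L``/``.R`` suffix
so that every node label is unique.  Indices are 1-based in every user-facing
table; 0-based indexing is an internal concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# (region name, abbreviation) for each homologous pair, in atlas index order:
# pair k occupies 1-based indices (2k+1, 2k+2) = (left, right).
_AAL90_PAIRS: list[tuple[str, str]] = [
    ("Superior frontal gyrus, dorsolateral", "SFGdor"),
    ("Middle frontal gyrus", "MFG"),
    ("Inferior frontal gyrus, opercular part", "IFGoperc"),
    ("Inferior frontal gyrus, triangular part", "IFGtriang"),
    ("Rolandic operculum", "ROL"),
    ("Supplementary motor area", "SMA"),
    ("Superior frontal gyrus, medial", "SFGmed"),
    ("Cuneus", "CUN"),
    ("Lingual gyrus", "LING"),
    ("Superior occipital gyrus", "SOG"),
    ("Middle occipital gyrus", "MOG"),
    ("Inferior occipital gyrus", "IOG"),
    ("Fusiform gyrus", "FFG"),
    ("Superior parietal gyrus", "SPG"),
    ("Inferior parietal, but supramarginal and angular gyri", "IPL"),
    ("Supramarginal gyrus", "SMG"),
    ("Angular gyrus", "ANG"),
    ("Precuneus", "PCUN"),
    ("Paracentral lobule", "PCL"),
    ("Superior temporal gyrus", "STG"),
    ("Middle temporal gyrus", "MTG"),
    ("Inferior temporal gyrus", "ITG"),
    ("Superior frontal gyrus, orbital part", "ORBsup"),
    ("Middle frontal gyrus, orbital part", "ORBmid"),
    ("Inferior frontal gyrus, orbital part", "ORBinf"),
    ("Superior frontal gyrus, medial orbital", "ORBsupmed"),
    ("Gyrus rectus", "REC"),
    ("Insula", "INS"),
    ("Anterior cingulate and paracingulate gyri", "ACG"),
    ("Median cingulate and paracingulate gyri", "DCG"),
    ("Posterior cingulate gyrus", "PCG"),
    ("Parahippocampal gyrus", "PHG"),
    ("Temporal pole: superior temporal gyrus", "TPOsup"),
    ("Temporal pole: middle temporal gyrus", "TPOmid"),
    ("Olfactory cortex", "OLF"),
    ("Hippocampus", "HIP"),
    ("Amygdala", "AMYG"),
    ("Caudate nucleus", "CAU"),
    ("Lenticular nucleus, putamen", "PUT"),
    ("Lenticular nucleus, pallidum", "PAL"),
    ("Thalamus", "THA"),
    ("Precental gyrus", "PreCG"),
    ("Calcarine fissure and surrounding cortex", "CAL"),
    ("Postcentral gyrus", "PoCG"),
    ("Heschl gyrus", "HES"),
]


@dataclass
class NodeLabelTable:
    """Region index / name / abbreviation table, optionally with centroids.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``index`` (1-based, contiguous), ``name``, ``abbreviation``
        and optionally ``x``, ``y``, ``z`` centroid coordinates used for
        BrainNet-Viewer-style ``.node`` export.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("index", "name", "abbreviation"):
            if col not in t.columns:
                raise ValueError(f"node-label table lacks column {col!r}")
        idx = np.asarray(t["index"], dtype=int)
        n = len(idx)
        if sorted(idx) != list(range(1, n + 1)):
            raise ValueError("node indices must be unique and contiguous from 1")
        if t["abbreviation"].duplicated().any():
            dup = t.loc[t["abbreviation"].duplicated(), "abbreviation"].iloc[0]
            raise ValueError(f"duplicate node abbreviation {dup!r}")
        self.table = t.sort_values("index").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def abbreviations(self) -> list[str]:
        return list(self.table["abbreviation"])

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def coordinates(self) -> np.ndarray:
        """Centroid coordinates, or zeros when none were supplied."""
        if {"x", "y", "z"} <= set(self.table.columns):
            return self.table[["x", "y", "z"]].to_numpy(dtype=float)
        return np.zeros((len(self), 3))

    @classmethod
    def from_tsv(cls, path) -> "NodeLabelTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def aal90_labels() -> NodeLabelTable:
    """The standard 90-region table (45 homologous pairs, left then right)."""
    rows = []
    for k, (name, abbr) in enumerate(_AAL90_PAIRS):
        rows.append((2 * k + 1, f"{name} (left)", f"{abbr}.L"))
        rows.append((2 * k + 2, f"{name} (right)", f"{abbr}.R"))
    return NodeLabelTable(
        pd.DataFrame(rows, columns=["index", "name", "abbreviation"])
    )


def generic_labels(n_rois: int) -> NodeLabelTable:
    """Placeholder labels (ROI001...) for simulations at arbitrary sizes."""
    if n_rois == 90:
        return aal90_labels()
    rows = [(i + 1, f"Region {i + 1}", f"ROI{i + 1:03d}") for i in range(n_rois)]
    return NodeLabelTable(pd.DataFrame(rows, columns=["index", "name", "abbreviation"]))
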