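"""The per-region container every fine-mapping engine consumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from finelocus.ldtools import LDMatrix, SummaryStats


@dataclass
class Locus:
    """SNP identities, summary statistics, LD and optional annotations for one region."""

    stats: SummaryStats
    ld: LDMatrix
    annotations: np.ndarray | None = None  # m x a binary matrix

    def __post_init__(self) -> None:
        if self.stats.m != self.ld.m:
            raise ValueError("summary statistics and LD matrix disagree on SNP count")
        if list(self.stats.ids) != list(self.ld.variant_ids):
            raise ValueError("summary statistics and LD matrix variant ids differ")
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations)
            if self.annotations.ndim == 1:
                self.annotations = self.annotations[:, None]
            if self.annotations.shape[0] != self.stats.m:
                raise ValueError("annotation rows must match SNP count")
            if not np.isin(self.annotations, (0, 1)).all():
                raise ValueError("annotations must be binary")

    @property
    def m(self) -> int:
        return self.stats.m

    @property
    def z(self) -> np.ndarray:
        return self.stats.z

    @property
    def ids(self) -> list[str]:
        return list(self.stats.ids)
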