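"""Core value types shared across the package.

A transcript is identified by a gene ``base_id`` plus a strand tag; the
anti-sense partner of gene ``g`` renders as ``g_AS``.  An expression matrix
is a (transcripts x samples) array of normalized log2 intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Strand",
    "TranscriptID",
    "ExpressionMatrix",
    "DEResult",
]

_AS_SUFFIX = "_AS"


class Strand(str, Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"


@dataclass(frozen=True, order=True)
class TranscriptID:
    """Gene identifier plus strand; ``str()`` is stable and bijective."""

    base_id: str
    strand: Strand = Strand.SENSE

    def __str__(self) -> str:
        if self.strand is Strand.ANTISENSE:
            return self.base_id + _AS_SUFFIX
        return self.base_id

    @property
    def is_sense(self) -> bool:
        return self.strand is Strand.SENSE

    @property
    def is_antisense(self) -> bool:
        return self.strand is Strand.ANTISENSE

    def couple(self) -> "TranscriptID":
        """The complementary transcript on the other strand."""
        other = Strand.ANTISENSE if self.is_sense else Strand.SENSE
        return TranscriptID(self.base_id, other)

    @classmethod
    def parse(cls, text: str) -> "TranscriptID":
        if text.endswith(_AS_SUFFIX):
            return cls(text[: -len(_AS_SUFFIX)], Strand.ANTISENSE)
        return cls(text, Strand.SENSE)


@dataclass
class ExpressionMatrix:
    """Transcripts x samples real matrix with labelled axes.

    ``values[i, j]`` is the intensity of ``transcripts[i]`` in
    ``samples[j]``.  No missing values are allowed.
    """

    transcripts: list[TranscriptID]
    samples: list[str]
    values: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_t, n_s = self.values.shape
        if n_t != len(self.transcripts):
            raise ValueError(
                f"row count {n_t} != transcript count {len(self.transcripts)}"
            )
        if n_s != len(self.samples):
            raise ValueError(
                f"column count {n_s} != sample count {len(self.samples)}"
            )
        if len({str(t) for t in self.transcripts}) != len(self.transcripts):
            raise ValueError("duplicate transcript IDs")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def index_of(self, transcript: TranscriptID | str) -> int:
        key = str(transcript)
        for i, t in enumerate(self.transcripts):
            if str(t) == key:
                return i
        raise KeyError(key)

    def subset_transcripts(
        self, keep: Iterable[TranscriptID | str]
    ) -> "ExpressionMatrix":
        keys = {str(k) for k in keep}
        idx = [i for i, t in enumerate(self.transcripts) if str(t) in keys]
        return ExpressionMatrix(
            [self.transcripts[i] for i in idx],
            list(self.samples),
            self.values[idx, :],
            condition=self.condition,
        )

    def subset_samples(self, cols: Sequence[int]) -> "ExpressionMatrix":
        cols = list(cols)
        return ExpressionMatrix(
            list(self.transcripts),
            [self.samples[j] for j in cols],
            self.values[:, cols],
            condition=self.condition,
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=np.asarray(values, dtype=float))

    def sense_only(self) -> "ExpressionMatrix":
        return self.subset_transcripts(
            t for t in self.transcripts if t.is_sense
        )


@dataclass(frozen=True)
class DEResult:
    """Per-transcript differential-expression outcome."""

    transcript: TranscriptID
    p_value: float
    log_fold_change: float
    is_de: bool = field(default=False, compare=False)
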