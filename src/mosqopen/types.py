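"""Core containers: activation records and sets.

An *activation vector* (the pre-softmax logits ``z`` of a closed-set
classifier, one component per known class) is the universal currency of the
toolkit: any external model can export a delimited table of them, and every
open-set operation downstream consumes them.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

#: Reserved label for samples that belong to no known class.
UNKNOWN_LABEL = "__unknown__"

#: Significant digits used when writing floats to delimited tables.
TABLE_FLOAT_DIGITS = 9


@dataclass(frozen=True)
class ActivationRecord:
    """One sample: identifier, true label, and its M-dimensional activation vector."""

    sample_id: str
    label: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.ndim != 1:
            raise InvalidArgumentError(
                f"activation vector of {self.sample_id!r} must be 1-D, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError(
                f"activation vector of {self.sample_id!r} contains non-finite entries"
            )
        object.__setattr__(self, "vector", v)


class ActivationSet:
    """An ordered collection of :class:`ActivationRecord` with table I/O."""

    def __init__(self, records: Iterable[ActivationRecord]):
        self.records: list[ActivationRecord] = list(records)
        if self.records:
            dim = self.records[0].vector.size
            for r in self.records:
                if r.vector.size != dim:
                    raise InvalidArgumentError(
                        f"inconsistent vector length: {r.sample_id!r} has {r.vector.size}, expected {dim}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ActivationRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ActivationRecord:
        return self.records[i]

    @property
    def dim(self) -> int:
        if not self.records:
            raise InvalidArgumentError("empty activation set has no dimension")
        return self.records[0].vector.size

    def ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def matrix(self) -> np.ndarray:
        """All vectors stacked row-wise, shape (n, M)."""
        return np.vstack([r.vector for r in self.records])

    def known_labels(self, unknown_label: str = UNKNOWN_LABEL) -> list[str]:
        """Sorted unique labels excluding the unknown marker."""
        return sorted({r.label for r in self.records} - {unknown_label})

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        m = self.matrix() if self.records else np.empty((0, 0))
        cols = {f"a{i}": m[:, i] for i in range(m.shape[1])}
        return pd.DataFrame({"sample_id": self.ids(), "label": self.labels(), **cols})

    def to_text(self, delimiter: str = "\t") -> str:
        """Serialize as a delimited table, floats at 9 significant digits."""
        buf = _io.StringIO()
        self.to_frame().to_csv(
            buf, sep=delimiter, index=False, float_format=f"%.{TABLE_FLOAT_DIGITS}g"
        )
        return buf.getvalue()

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        Path(path).write_text(self.to_text(delimiter))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ActivationSet":
        acols = [c for c in df.columns if c.startswith("a") and c[1:].isdigit()]
        acols.sort(key=lambda c: int(c[1:]))
        recs = [
            ActivationRecord(str(row.sample_id), str(row.label), np.array([getattr(row, c) for c in acols], dtype=float))
            for row in df.itertuples(index=False)
        ]
        return cls(recs)

    @classmethod
    def read(cls, path: str | Path, delimiter: str | None = None) -> "ActivationSet":
        if delimiter is None:
            delimiter = "," if str(path).endswith(".csv") else "\t"
        return cls.from_frame(pd.read_csv(path, sep=delimiter))

    @classmethod
    def concat(cls, sets: Sequence["ActivationSet"]) -> "ActivationSet":
        recs: list[ActivationRecord] = []
        for s in sets:
            recs.extend(s.records)
        return cls(recs)
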