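"""Equilibrium-magnetization map container with option provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class M0Map:
    """A tissue (M0t) or arterial (M0a) equilibrium-magnetization map.

    ``values`` is a volume, or a scalar for reference-tissue-derived M0a.
    ``method`` and ``meta`` carry the full provenance of how the map was
    produced (every comparison downstream is keyed on them).
    """

    values: np.ndarray | float
    kind: str                     # "M0t" | "M0a"
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def is_scalar(self) -> bool:
        return np.ndim(self.values) == 0

    def provenance(self) -> dict:
        return {"kind": self.kind, "method": self.method, **self.meta}

    def save(self, path_prefix: str | Path) -> None:
        """Write values (.npy or scalar inline) plus a JSON provenance file."""
        path_prefix = Path(path_prefix)
        doc = {"kind": self.kind, "method": self.method, "meta": self.meta}
        if self.is_scalar:
            doc["scalar_value"] = float(self.values)
        else:
            np.save(path_prefix.with_suffix(".npy"), np.asarray(self.values))
            doc["values_file"] = path_prefix.with_suffix(".npy").name
        path_prefix.with_suffix(".json").write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path_prefix: str | Path) -> "M0Map":
        path_prefix = Path(path_prefix)
        doc = json.loads(path_prefix.with_suffix(".json").read_text())
        if "scalar_value" in doc:
            values = float(doc["scalar_value"])
        else:
            values = np.load(path_prefix.parent / doc["values_file"])
        return cls(values=values, kind=doc["kind"], method=doc["method"],
                   meta=doc["meta"])
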