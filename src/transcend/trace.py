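"""Time-indexed record stream: the unit of analysis for all experiments.

A trace is an ordered list of flat JSON-able records.  Every record has a
``kind`` (manifest | action | signal | declaration | sanction | obs |
belief | comparison | expansion | summary | ...) and, except for the
manifest, a ``tick``.  Metrics are computed from traces alone, so any
figure is reproducible from the trace file.  Indices inside records are
0-based; human-readable report headers state this explicitly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Iterable


@dataclass
class Trace:
    records: list[dict[str, Any]] = field(default_factory=list)

    def add(self, record: dict[str, Any]) -> None:
        self.records.append(record)

    def of_kind(self, kind: str) -> list[dict[str, Any]]:
        return [r for r in self.records if r.get("kind") == kind]

    @property
    def manifest(self) -> dict[str, Any]:
        for r in self.records:
            if r.get("kind") == "manifest":
                return r
        raise KeyError("trace has no manifest record")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    # -- I/O ---------------------------------------------------------------
    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r) + "\n")

    @classmethod
    def read_jsonl(cls, path) -> "Trace":
        with open(path) as fh:
            return cls([json.loads(line) for line in fh if line.strip()])


def config_hash(config_dict: dict[str, Any]) -> str:
    """Stable short hash of a config mapping, for trace manifests."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def make_manifest(config_dict: dict[str, Any], seed: int, **extra: Any) -> dict[str, Any]:
    return {
        "kind": "manifest",
        "schema_version": 1,
        "index_base": "0-based indices; human-readable reports are 1-based",
        "config_hash": config_hash(config_dict),
        "seed": seed,
        **extra,
    }


def check_monotone_ticks(records: Iterable[dict[str, Any]]) -> bool:
    last = -1
    for r in records:
        t = r.get("tick")
        if t is None:
            continue
        if t < last:
            return False
        last = t
    return True
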