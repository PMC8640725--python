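"""The 32-condition long-term-condition (LTC) catalogue.

Each condition carries a short code, a display name, a flag saying whether a
resolution/remission date can be recorded for it (true for 12 of the 32), and
a co-occurrence cluster label A-F:

    A  mental health (anxiety, depression)
    B  cardiovascular (heart failure, AF, CKD, CHD, stroke/TIA, PAD,
       dementia, osteoporosis)
    C  pain (osteoarthritis, cancer, chronic pain, hypertension, diabetes)
    D  liver disease (chronic liver disease, viral hepatitis)
    E  dependence (substance and alcohol dependency, HIV)
    F  conditions not strongly tied to any cluster

The default catalogue ships with the package; a custom one can be loaded
from any CSV with the same columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

CLUSTERS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class Condition:
    code: str
    name: str
    resolvable: bool
    cluster: str


class Catalogue:
    """Immutable lookup table over the condition set."""

    def __init__(self, conditions: list[Condition]):
        if len({c.code for c in conditions}) != len(conditions):
            raise ValueError("duplicate condition codes in catalogue")
        bad = [c.code for c in conditions if c.cluster not in CLUSTERS]
        if bad:
            raise ValueError(f"unknown cluster label for conditions: {bad}")
        self._by_code = {c.code: c for c in conditions}
        self.codes = tuple(c.code for c in conditions)

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Condition:
        return self._by_code[code]

    def __iter__(self):
        return iter(self._by_code.values())

    @property
    def resolvable_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self if c.resolvable)

    def cluster_of(self, code: str) -> str:
        return self._by_code[code].cluster

    def cluster_members(self, cluster: str) -> tuple[str, ...]:
        return tuple(c.code for c in self if c.cluster == cluster)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(c.code, c.name, int(c.resolvable), c.cluster) for c in self],
            columns=["code", "name", "resolvable", "cluster"],
        )


def load_catalogue(path: str | Path | None = None) -> Catalogue:
    """Load the condition catalogue from CSV (the packaged default if None)."""
    if path is None:
        ref = resources.files("mmtraj.data").joinpath("catalogue.csv")
        text = ref.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    required = {"code", "name", "resolvable", "cluster"}
    if rows and not required.issubset(rows[0].keys()):
        missing = required - set(rows[0].keys())
        raise ValueError(f"catalogue missing columns: {sorted(missing)}")
    conditions = [
        Condition(
            code=r["code"],
            name=r["name"],
            resolvable=bool(int(r["resolvable"])),
            cluster=r["cluster"],
        )
        for r in rows
    ]
    return Catalogue(conditions)


_DEFAULT: Catalogue | None = None


def default_catalogue() -> Catalogue:
    """The packaged 32-condition catalogue (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_catalogue()
    return _DEFAULT
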