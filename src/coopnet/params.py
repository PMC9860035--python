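"""Game and institution parameters.

Six scalars describe a group playing a linear public-goods game embedded in a
monitoring/punishment network:

``N``
    number of individuals (nodes).
``b``
    public-goods efficiency: contributions to the public good are multiplied
    by ``b`` and shared equally among the *other* ``N - 1`` individuals.
``m``
    monitoring efficiency: effectively monitoring one individual costs
    ``1/m``, so a node with out-degree ``k_out`` pays ``k_out / m``.
``p``
    punishment efficiency: a punisher who spends ``x`` on punishment inflicts
    a loss of ``p * x`` on the punished individual.
``c_t``
    contribution threshold: the total amount a contributor pays toward
    monitoring, punishment reserve and the public good.
``c_p``
    punishment reserve: the amount any node with monitoring responsibilities
    holds back to punish free-riders it monitors (``0 < c_p <= c_t``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

__all__ = ["GameParams"]

_FIELDS = ("N", "b", "m", "p", "c_t", "c_p")


@dataclass(frozen=True)
class GameParams:
    """Immutable bundle of the six model parameters, validated on creation."""

    N: int
    b: float
    m: float
    p: float
    c_t: float
    c_p: float

    def __post_init__(self) -> None:
        if not isinstance(self.N, int) or isinstance(self.N, bool):
            raise TypeError(f"N must be an integer, got {self.N!r}")
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.b < 1:
            raise ValueError(f"public-goods efficiency b must be >= 1, got {self.b}")
        if self.m <= 0:
            raise ValueError(f"monitoring efficiency m must be > 0, got {self.m}")
        if self.p <= 0:
            raise ValueError(f"punishment efficiency p must be > 0, got {self.p}")
        if self.c_t <= 0:
            raise ValueError(f"contribution threshold c_t must be > 0, got {self.c_t}")
        if not (0 < self.c_p <= self.c_t):
            raise ValueError(
                f"punishment reserve c_p must satisfy 0 < c_p <= c_t, "
                f"got c_p={self.c_p}, c_t={self.c_t}"
            )

    def replace(self, **changes: Any) -> "GameParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in _FIELDS}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "GameParams":
        missing = [f for f in _FIELDS if f not in mapping]
        if missing:
            raise KeyError(f"missing parameter(s): {', '.join(missing)}")
        return cls(
            N=int(mapping["N"]),
            b=float(mapping["b"]),
            m=float(mapping["m"]),
            p=float(mapping["p"]),
            c_t=float(mapping["c_t"]),
            c_p=float(mapping["c_p"]),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "GameParams":
        """Load parameters from a JSON or YAML file keyed by the field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path} does not contain a parameter mapping")
        return cls.from_mapping(data)
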