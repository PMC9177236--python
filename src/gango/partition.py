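"""Parcel → module (resting-state network) assignments."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of every node to exactly one named module.

    ``labels[i]`` is the module label of node ``i``. Module order is the
    order of first appearance, which keeps downstream tables stable.
    """

    labels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def module_names(self) -> list:
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def members(self, module: str) -> list:
        """Node indices belonging to ``module``."""
        return [i for i, lab in enumerate(self.labels) if lab == module]

    def as_indices(self) -> list:
        """Per-node module index, following :attr:`module_names` order."""
        order = {m: k for k, m in enumerate(self.module_names)}
        return [order[lab] for lab in self.labels]
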