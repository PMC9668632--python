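"""Resting-state network (RSN) assignment of signal components.

Components extracted from group ICA are assigned to one of eight canonical
resting-state networks: ventral attention (vATT), dorsal attention (dATT),
somatomotor (SMN), default mode (DMN), visual (VIS), frontoparietal (FPN),
basal ganglia (BG) and cerebellum (CB).  The BG network may legitimately
contain a single component.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

NETWORK_NAMES: tuple[str, ...] = (
    "vATT", "dATT", "SMN", "DMN", "VIS", "FPN", "BG", "CB",
)

# Default component counts per network for the 47-component layout.
# BG holds exactly one (bilateral basal ganglia) component.
_DEFAULT_SIZES: dict[str, int] = {
    "vATT": 5, "dATT": 6, "SMN": 9, "DMN": 10,
    "VIS": 8, "FPN": 6, "BG": 1, "CB": 2,
}


@dataclass(frozen=True)
class NetworkAssignment:
    """Maps each component id to exactly one RSN label."""

    mapping: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty network assignment")
        bad = {n for n in self.mapping.values() if n not in NETWORK_NAMES}
        if bad:
            raise ValueError(f"unknown network labels: {sorted(bad)}")

    @property
    def component_ids(self) -> list[str]:
        return list(self.mapping)

    @property
    def networks(self) -> list[str]:
        """Networks actually present, in canonical order."""
        present = set(self.mapping.values())
        return [n for n in NETWORK_NAMES if n in present]

    def components(self, network: str) -> list[str]:
        return [c for c, n in self.mapping.items() if n == network]

    def network_of(self, component: str) -> str:
        return self.mapping[component]

    def size(self, network: str) -> int:
        return len(self.components(network))

    def multi_component_networks(self) -> list[str]:
        """Networks with >= 2 components (the only ones with intra-network pairs)."""
        return [n for n in self.networks if self.size(n) >= 2]

    def check_covers(self, component_ids: Sequence[str]) -> list[str]:
        """Return the component ids that are missing from the assignment."""
        return [c for c in component_ids if c not in self.mapping]


def default_assignment(n_components: int = 47) -> NetworkAssignment:
    """Default 8-network assignment of ``n_components`` components.

    For the canonical 47-component layout the network sizes are
    vATT=5, dATT=6, SMN=9, DMN=10, VIS=8, FPN=6, BG=1, CB=2.  For other
    component counts the same proportions are used, with BG pinned to a
    single component.
    """
    if n_components < len(NETWORK_NAMES):
        raise ValueError("need at least one component per network")
    if n_components == 47:
        sizes = dict(_DEFAULT_SIZES)
    else:
        sizes = {"BG": 1}
        rest = n_components - 1
        others = [n for n in NETWORK_NAMES if n != "BG"]
        base = rest // len(others)
        extra = rest - base * len(others)
        for i, n in enumerate(others):
            sizes[n] = base + (1 if i < extra else 0)
    ids = [f"IC{i + 1:02d}" for i in range(n_components)]
    mapping: dict[str, str] = {}
    k = 0
    for net in NETWORK_NAMES:
        for _ in range(sizes[net]):
            mapping[ids[k]] = net
            k += 1
    return NetworkAssignment(mapping)
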