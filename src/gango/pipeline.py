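"""End-to-end per-subject pipeline: gate → adjacency search → orientation."""

from __future__ import annotations

from .errors import DegenerateDataError
from .fges import fges, symmetrize
from .gate import GateResult, gate_subject
from .graphs import DirectedConnectome
from .orientation import orient_edges

__all__ = ["GateRefusalError", "fit_connectome", "gango"]


class GateRefusalError(DegenerateDataError):
    """Raised when the skewness gate fails and orientation is not forced."""

    def __init__(self, result: GateResult):
        self.gate_result = result
        super().__init__(
            "data are not significantly skewed "
            f"(rank-sum p = {result.p_value:.3g} >= alpha = {result.alpha}); "
            "skew-based orientation would be at chance. Pass force=True to override."
        )


def fit_connectome(
    ts,
    penalty: float = 1.0,
    gate_alpha: float = 0.05,
    seed: int = 0,
    force: bool = False,
) -> tuple[DirectedConnectome, GateResult]:
    """Full pipeline with the gate-before-orient policy.

    Orientation is only meaningful on skewed data, so the pipeline
    refuses to orient when the gate fails unless ``force`` is set.
    """
    result = gate_subject(ts, alpha=gate_alpha, seed=seed)
    if not result.passed and not force:
        raise GateRefusalError(result)
    pattern = fges(ts, penalty=penalty)
    return orient_edges(symmetrize(pattern), ts), result


def gango(ts, penalty: float = 1.0) -> DirectedConnectome:
    """Adjacency search then orientation, without the gate (deterministic)."""
    return orient_edges(symmetrize(fges(ts, penalty=penalty)), ts)
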