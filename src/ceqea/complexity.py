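"""Analytic token / attention / communication accounting.

Self-attention over ``N`` tokens computes ``N^2`` pairwise scores per
layer per head, so pruning to ``K`` retained tokens cuts the dominant
encoder cost by ``1 - K^2/N^2``.  Faster convergence additionally cuts
federated communication in proportion to the saved rounds.  These are
closed-form quantities; this module computes and formats them.

Rounding follows report conventions: percentages to one decimal,
speedups to two decimals, half-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "attention_ops",
    "pruning_ratio_pct",
    "attention_reduction_pct",
    "retained_factor_pct",
    "comm_reduction_pct",
    "speedup",
    "ComplexityReport",
    "build_report",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check(n: int, k: int) -> None:
    if n <= 0:
        raise ValueError("token count N must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"retained count K={k} must lie in [0, N={n}]")


def attention_ops(n: int) -> int:
    """Pairwise attention scores for an ``n``-token sequence: ``n^2``."""
    if n < 0:
        raise ValueError("token count must be non-negative")
    return n * n


def pruning_ratio_pct(n: int, k: int) -> float:
    """Fraction of tokens removed, ``100 (N - K)/N``, one decimal."""
    _check(n, k)
    return round_half_up(100.0 * (n - k) / n, 1)


def attention_reduction_pct(n: int, k: int, ndigits: int = 1) -> float:
    """Attention-cost saving ``100 (1 - K^2/N^2)``."""
    _check(n, k)
    return round_half_up(100.0 * (1.0 - (k * k) / (n * n)), ndigits)


def retained_factor_pct(n: int, k: int, ndigits: int = 0) -> float:
    """Residual attention cost ``100 K^2/N^2`` (complement of the above)."""
    _check(n, k)
    return round_half_up(100.0 * (k * k) / (n * n), ndigits)


def comm_reduction_pct(rounds_base: int, rounds_pruned: int) -> float:
    """Communication saved by converging in fewer rounds, one decimal."""
    if rounds_base <= 0 or rounds_pruned <= 0:
        raise ValueError("round counts must be positive")
    return round_half_up(100.0 * (rounds_base - rounds_pruned) / rounds_base, 1)


def speedup(rounds_base: int, rounds_pruned: int) -> float:
    """Convergence speedup ``base / pruned``, two decimals."""
    if rounds_base <= 0 or rounds_pruned <= 0:
        raise ValueError("round counts must be positive")
    return round_half_up(rounds_base / rounds_pruned, 2)


@dataclass(frozen=True)
class ComplexityReport:
    """Side-by-side accounting for a full vs pruned federated encoder."""

    n_tokens: int
    retained: int
    attention_ops_full: int
    attention_ops_pruned: int
    pruning_ratio_pct: float
    attention_reduction_pct: float
    retained_factor_pct: float
    rounds_baseline: int
    rounds_pruned: int
    comm_reduction_pct: float
    speedup: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        rows = [
            ("Total tokens per image (N)", self.n_tokens, self.n_tokens),
            ("Tokens retained after pruning (K)", self.n_tokens, self.retained),
            ("Token pruning ratio (%)", 0.0, self.pruning_ratio_pct),
            ("Attention operations (N^2)", self.attention_ops_full, self.attention_ops_pruned),
            ("Attention complexity reduction (%)", 0.0, self.attention_reduction_pct),
            ("Retained attention factor (%)", 100.0, self.retained_factor_pct),
            ("FL rounds to target accuracy", self.rounds_baseline, self.rounds_pruned),
            ("Total communication reduction (%)", 0.0, self.comm_reduction_pct),
            ("Convergence speedup (x)", 1.0, self.speedup),
        ]
        w = max(len(r[0]) for r in rows)
        lines = [f"{'Metric':<{w}}  {'Full':>10}  {'Pruned':>10}"]
        lines += [f"{name:<{w}}  {full:>10}  {pruned:>10}" for name, full, pruned in rows]
        return "\n".join(lines)


def build_report(n_tokens: int, retained: int, rounds_baseline: int, rounds_pruned: int) -> ComplexityReport:
    _check(n_tokens, retained)
    return ComplexityReport(
        n_tokens=n_tokens,
        retained=retained,
        attention_ops_full=attention_ops(n_tokens),
        attention_ops_pruned=attention_ops(retained),
        pruning_ratio_pct=pruning_ratio_pct(n_tokens, retained),
        attention_reduction_pct=attention_reduction_pct(n_tokens, retained),
        retained_factor_pct=retained_factor_pct(n_tokens, retained, ndigits=1),
        rounds_baseline=rounds_baseline,
        rounds_pruned=rounds_pruned,
        comm_reduction_pct=comm_reduction_pct(rounds_baseline, rounds_pruned),
        speedup=speedup(rounds_baseline, rounds_pruned),
    )
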