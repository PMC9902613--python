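"""Parametric substitution/insertion/deletion channel and BER sweep harness.

`corrupt` applies i.i.d. per-base events: an insertion of a uniform base may
be placed before each position, the position itself may be deleted, and an
undeleted base may be substituted by a uniformly chosen different base.
`sweep` runs the full encode-corrupt-decode pipeline over a BER grid in two
modes: substitution-only, or a mixed-indel mode that scales the measured
high-mutagenesis rates (substitution 0.0238, deletion 0.0082, insertion
0.0039) by a common multiplier so their sum matches the grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import BASES

#: per-base error rates measured with a high-mutagenesis kit, used as the
#: mixed-mode proportions (substitution : deletion : insertion)
HIGH_MUTAGENESIS_SUB = 0.0238
HIGH_MUTAGENESIS_DEL = 0.0082
HIGH_MUTAGENESIS_INS = 0.0039


@dataclass(frozen=True)
class ErrorRates:
    sub: float = 0.0
    ins: float = 0.0
    dele: float = 0.0
    multiplier: float = 1.0

    def __post_init__(self):
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")
        for r in self.effective():
            if not (0.0 <= r <= 1.0):
                raise ValueError("effective rates must be in [0, 1]")

    def effective(self) -> tuple[float, float, float]:
        return (self.sub * self.multiplier,
                self.ins * self.multiplier,
                self.dele * self.multiplier)


def high_mutagenesis(multiplier: float = 1.0) -> ErrorRates:
    return ErrorRates(HIGH_MUTAGENESIS_SUB, HIGH_MUTAGENESIS_INS,
                      HIGH_MUTAGENESIS_DEL, multiplier)


def mixed_rates_for_ber(ber: float) -> ErrorRates:
    """Scale the high-mutagenesis proportions to an aggregate per-base rate."""
    total = HIGH_MUTAGENESIS_SUB + HIGH_MUTAGENESIS_DEL + HIGH_MUTAGENESIS_INS
    return high_mutagenesis(ber / total)


def corrupt(seq: str, rates: ErrorRates, seed: int | np.random.Generator) -> str:
    """Apply the error channel to one strand, deterministically for a seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_sub, p_ins, p_del = rates.effective()
    n = len(seq)
    if n == 0:
        return ""
    u = rng.random((n, 3))
    ins_base = rng.integers(0, 4, size=n)
    sub_shift = rng.integers(1, 4, size=n)
    out = []
    for j, ch in enumerate(seq):
        if u[j, 0] < p_ins:
            out.append(BASES[ins_base[j]])
        if u[j, 1] < p_del:
            continue
        if u[j, 2] < p_sub:
            out.append(BASES[(BASES.index(ch) + sub_shift[j]) % 4])
        else:
            out.append(ch)
    return "".join(out)


def sweep(data: bytes, model, params, ber_grid, reps: int, seed: int,
          mode: str = "substitution") -> pd.DataFrame:
    """Success-rate table over a BER grid for the full pipeline.

    Encoding is shared across grid points (only the channel differs between
    modes); each repetition corrupts every strand with a seed derived from
    (seed, grid index, repetition) and attempts an end-to-end decode.
    """
    from .pipeline import decode_strands, encode_file

    if mode not in ("substitution", "mixed"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    records, manifest = encode_file(data, model, params)
    strands = [s for _, s in records]
    rows = []
    for gi, ber in enumerate(ber_grid):
        if mode == "substitution":
            rates = ErrorRates(sub=float(ber))
        else:
            rates = mixed_rates_for_ber(float(ber))
        successes = 0
        for rep in range(reps):
            rng = np.random.default_rng(
                [seed, gi, rep] if seed is not None else None
            )
            noisy = [corrupt(s, rates, rng) for s in strands]
            try:
                decoded, _report = decode_strands(noisy, model, params, manifest)
                successes += int(decoded == data)
            except Exception:
                pass
        rows.append({"ber": float(ber), "reps": reps, "successes": successes,
                     "success_rate": successes / reps, "mode": mode,
                     "seed": seed})
    return pd.DataFrame(rows)
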