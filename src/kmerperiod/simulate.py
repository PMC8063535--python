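"""Synthetic sequence sets with controlled periodic structure.

Emulates the kind of signal the pipeline is built to detect — a short motif
recurring every ``period`` bp (e.g. TT every 10 bp, as in nucleosome-favoring
promoter sequences) — on top of an i.i.d. background, with tunable phase
jitter and site occupancy. Planting overwrites background letters in place,
so sequence length and downstream phases are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import DnaSequence

__all__ = ["PlantSpec", "make_random_sequences", "make_periodic_sequences"]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: a concrete motif every ``period`` bp.

    jitter_sd is the SD (bp) of the rounded Gaussian offset applied to each
    site; occupancy is the probability each planned site is actually planted.
    background gives per-letter probabilities (A, C, G, T).
    """

    motif: str
    period: int
    phase: int = 0
    jitter_sd: float = 0.0
    occupancy: float = 1.0
    background: tuple[float, float, float, float] = UNIFORM

    def __post_init__(self) -> None:
        if set(self.motif.upper()) - set("ACGT"):
            raise ValueError("planted motif must be a concrete A/C/G/T k-mer")
        if self.period < len(self.motif):
            raise ValueError(
                f"period ({self.period}) must be >= motif length ({len(self.motif)})"
            )
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        _check_background(self.background)


def _check_background(background) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 non-negative probabilities summing to 1")
    return bg


def make_random_sequences(
    n: int,
    length: int,
    background=UNIFORM,
    seed: int = 0,
) -> list[DnaSequence]:
    """n i.i.d. background sequences, deterministic given seed."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    bg = _check_background(background)
    rng = np.random.default_rng(seed)
    draws = rng.choice(_ALPHABET, size=(n, length), p=bg)
    return [
        DnaSequence(id=f"random_{i}", bases=row.tobytes().decode())
        for i, row in enumerate(draws)
    ]


def make_periodic_sequences(
    n: int,
    length: int,
    plant: PlantSpec,
    seed: int = 0,
) -> tuple[list[DnaSequence], dict]:
    """Background sequences with a motif planted periodically; plus the truth.

    Sites are planned at phase + i*period, offset by round(N(0, jitter_sd)),
    clipped to sequence bounds. A site overlapping the previous planted copy
    is skipped (recorded in the truth record), as is a site failing the
    occupancy draw. The truth record lists realized positions per sequence.
    """
    plant_motif = plant.motif.upper()
    k = len(plant_motif)
    if plant.phase + k > length:
        raise ValueError("phase + motif length must fit inside the sequence")
    rng = np.random.default_rng(seed)
    bg = _check_background(plant.background)
    motif_arr = np.frombuffer(plant_motif.encode(), dtype=np.uint8)

    seqs: list[DnaSequence] = []
    positions: list[list[int]] = []
    n_skipped_overlap = 0
    n_skipped_occupancy = 0
    planned = np.arange(plant.phase, length - k + 1, plant.period)
    for i in range(n):
        arr = rng.choice(_ALPHABET, size=length, p=bg)
        realized: list[int] = []
        prev_end = -1
        for site in planned:
            if plant.occupancy < 1.0 and rng.random() >= plant.occupancy:
                n_skipped_occupancy += 1
                continue
            pos = site
            if plant.jitter_sd > 0:
                pos = site + int(np.rint(rng.normal(0.0, plant.jitter_sd)))
            pos = int(np.clip(pos, 0, length - k))
            if pos < prev_end:
                n_skipped_overlap += 1
                continue
            arr[pos : pos + k] = motif_arr
            realized.append(pos)
            prev_end = pos + k
        seqs.append(DnaSequence(id=f"planted_{i}", bases=arr.tobytes().decode()))
        positions.append(realized)

    truth = {
        "motif": plant_motif,
        "period": plant.period,
        "phase": plant.phase,
        "jitter_sd": plant.jitter_sd,
        "occupancy": plant.occupancy,
        "background": list(bg),
        "seed": seed,
        "n": n,
        "length": length,
        "positions": positions,
        "n_skipped_overlap": n_skipped_overlap,
        "n_skipped_occupancy": n_skipped_occupancy,
    }
    return seqs, truth
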