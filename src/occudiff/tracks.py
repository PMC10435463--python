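"""Fixed-step coverage tracks and bedGraph interchange.

Coverage is held at a fixed step (default 50 bp) rather than per base, to
bound memory on genome-scale inputs; every downstream mean is length-weighted
so partial steps and partial bins are handled exactly. bedGraph intervals
that do not align to the step are averaged into steps by base-pair overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeLayout, GenomeFormatError, GenomeValidationError

DEFAULT_STEP = 50


def _n_steps(length: int, step: int) -> int:
    return -(-length // step)


@dataclass
class SignalTrack:
    """Per-chromosome fixed-step coverage values for one sample/replicate.

    ``data[chrom][i]`` is the mean per-bp signal over
    ``[i*step, min((i+1)*step, chrom_length))``.
    """

    layout: GenomeLayout
    step: int
    data: dict[str, np.ndarray]
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise GenomeValidationError("step must be positive")
        for name, length in self.layout.chromosomes:
            if name not in self.data:
                self.data[name] = np.zeros(_n_steps(length, self.step))
            elif len(self.data[name]) != _n_steps(length, self.step):
                raise GenomeValidationError(
                    f"track for {name}: expected {_n_steps(length, self.step)} steps, "
                    f"got {len(self.data[name])}"
                )

    @classmethod
    def zeros(cls, layout: GenomeLayout, step: int = DEFAULT_STEP) -> "SignalTrack":
        return cls(layout, step, {})

    def _cumulative(self, chrom: str) -> np.ndarray:
        """Prefix sums of per-step integrals (value × step length), cached."""
        if chrom not in self._cum:
            length = self.layout.length_of(chrom)
            vals = self.data[chrom]
            lens = np.full(len(vals), float(self.step))
            if length % self.step:
                lens[-1] = length % self.step
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(vals * lens)])
        return self._cum[chrom]

    def invalidate_cache(self) -> None:
        self._cum.clear()

    def _integral_at(self, chrom: str, pos: int) -> float:
        cum = self._cumulative(chrom)
        i = pos // self.step
        if i >= len(self.data[chrom]):
            return float(cum[-1])
        return float(cum[i] + self.data[chrom][i] * (pos - i * self.step))

    def integral(self, chrom: str, start: int, end: int) -> float:
        """∫ signal over [start, end) in value·bp units."""
        if not (0 <= start <= end <= self.layout.length_of(chrom)):
            raise GenomeValidationError(
                f"window [{start},{end}) outside {chrom} "
                f"(length {self.layout.length_of(chrom)})"
            )
        return self._integral_at(chrom, end) - self._integral_at(chrom, start)

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean signal over [start, end)."""
        if end <= start:
            raise GenomeValidationError("empty window")
        return self.integral(chrom, start, end) / (end - start)

    def window_mean_clipped(self, chrom: str, start: int, end: int) -> float:
        """Mean over the window treating out-of-bounds positions as zero signal."""
        length = self.layout.length_of(chrom)
        a, b = max(0, start), min(length, end)
        if b <= a:
            return 0.0
        return self.integral(chrom, a, b) / (end - start)

    def profile(self, chrom: str, start: int, end: int, n_bins: int,
                clip: bool = False) -> np.ndarray:
        """Length-weighted means over ``n_bins`` equal sub-bins of [start, end).

        Boundaries are ``start + round(i*len/n_bins)``. With ``clip=True``,
        positions outside the chromosome contribute zero signal (used for
        TSS-anchored windows near chromosome edges).
        """
        length = end - start
        if length < n_bins:
            raise GenomeValidationError(
                f"region of {length} bp cannot be split into {n_bins} sub-bins"
            )
        bounds = start + np.round(np.arange(n_bins + 1) * length / n_bins).astype(np.int64)
        out = np.empty(n_bins)
        fn = self.window_mean_clipped if clip else self.window_mean
        for i in range(n_bins):
            out[i] = fn(chrom, int(bounds[i]), int(bounds[i + 1]))
        return out


def read_bedgraph(path: str | Path, layout: GenomeLayout,
                  step: int = DEFAULT_STEP) -> SignalTrack:
    """Read a bedGraph into a fixed-step track; uncovered positions are zero.

    Intervals must be sorted and non-overlapping within each chromosome;
    boundaries that do not align to the step are averaged into steps by
    overlap length.
    """
    acc = {
        name: np.zeros(_n_steps(length, step))
        for name, length in layout.chromosomes
    }
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GenomeFormatError(f"{path}:{lineno}: need 4 bedGraph fields")
            chrom, s_s, e_s, v_s = parts[:4]
            if chrom not in layout:
                raise GenomeValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            s, e, v = int(s_s), int(e_s), float(v_s)
            if not (0 <= s < e <= layout.length_of(chrom)):
                raise GenomeValidationError(
                    f"{path}:{lineno}: interval [{s},{e}) outside {chrom}"
                )
            if s < last_end.get(chrom, 0):
                raise GenomeFormatError(
                    f"{path}:{lineno}: intervals overlap or are unsorted on {chrom}"
                )
            last_end[chrom] = e
            a = acc[chrom]
            i0, i1 = s // step, (e - 1) // step
            if i0 == i1:
                a[i0] += v * (e - s)
            else:
                a[i0] += v * ((i0 + 1) * step - s)
                a[i1] += v * (e - i1 * step)
                if i1 > i0 + 1:
                    a[i0 + 1:i1] += v * step
    data: dict[str, np.ndarray] = {}
    for name, length in layout.chromosomes:
        eff = np.full(_n_steps(length, step), float(step))
        if length % step:
            eff[-1] = length % step
        data[name] = acc[name] / eff
    return SignalTrack(layout, step, data)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging equal-valued runs; zero runs omitted."""
    with open(path, "w") as fh:
        for name, length in track.layout.chromosomes:
            vals = track.data[name]
            if len(vals) == 0:
                continue
            run_start = 0
            run_val = vals[0]
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != run_val:
                    if run_val != 0.0:
                        s = run_start * track.step
                        e = min(i * track.step, length)
                        fh.write(f"{name}\t{s}\t{e}\t{run_val:g}\n")
                    if i < len(vals):
                        run_start, run_val = i, vals[i]
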