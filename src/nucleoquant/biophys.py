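"""Non-imaging biophysics utilities.

Chemical-shift perturbation and binding-residue flagging for ¹H-¹⁵N HSQC
titrations, molecule-count to molar-concentration conversion, protein
isoelectric point via Henderson-Hasselbalch charge balance, and an RNA/DNA
G-quadruplex motif scanner with per-region counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .errors import ContractError

# -- NMR chemical-shift perturbation ------------------------------------------

#: weight applied to the nitrogen dimension so H and N shifts are comparable
N_SHIFT_WEIGHT = 0.2
#: fractional peak-volume loss above which a residue is flagged
VOLUME_LOSS_CUTOFF = 2.0 / 3.0


def csp(delta_H, delta_N):
    """Combined amide chemical-shift perturbation, ppm.

    ``Δδ = sqrt(ΔδH² + (0.2·ΔδN)²)`` — symmetric in the sign of either shift
    and never smaller than |ΔδH| or 0.2·|ΔδN|.  Accepts scalars or arrays.
    """
    return np.hypot(np.asarray(delta_H, dtype=float),
                    N_SHIFT_WEIGHT * np.asarray(delta_N, dtype=float))


@dataclass
class PeakRecord:
    """One assigned amide cross-peak in the free and bound spectra."""

    residue_id: str
    delta_H: float
    delta_N: float
    volume_free: float
    volume_bound: float

    def __post_init__(self) -> None:
        if self.volume_free < 0 or self.volume_bound < 0:
            raise ContractError("peak volumes must be non-negative")


def flag_binding_residues(peaks) -> pd.DataFrame:
    """Flag residues by strong volume loss or above-mean shift perturbation.

    A residue is flagged ``volume_loss`` when it loses more than 2/3 of its
    free-state peak volume on binding, and ``shift_above_mean`` when its Δδ
    strictly exceeds the mean Δδ over all usable peaks.  Records with zero
    free volume are skipped with a warning.  Accepts a list of
    :class:`PeakRecord` or a DataFrame with the same fields.
    """
    if isinstance(peaks, pd.DataFrame):
        records = [PeakRecord(**row) for row in peaks.to_dict("records")]
    else:
        records = list(peaks)
    if not records:
        raise ContractError("need at least one peak")

    usable = []
    for p in records:
        if p.volume_free == 0:
            warnings.warn(f"peak {p.residue_id}: zero free volume, skipped",
                          stacklevel=2)
            continue
        usable.append(p)
    if not usable:
        raise ContractError("no usable peaks (all zero free volume)")

    shifts = csp([p.delta_H for p in usable], [p.delta_N for p in usable])
    mean_shift = float(shifts.mean())
    rows = []
    for p, dd in zip(usable, shifts):
        loss = (p.volume_free - p.volume_bound) / p.volume_free
        rows.append(
            {
                "residue_id": p.residue_id,
                "delta_shift": float(dd),
                "volume_loss_frac": float(loss),
                "volume_loss": bool(loss > VOLUME_LOSS_CUTOFF),
                "shift_above_mean": bool(dd > mean_shift),
            }
        )
    out = pd.DataFrame(rows)
    out["flagged"] = out["volume_loss"] | out["shift_above_mean"]
    return out


# -- concentration ------------------------------------------------------------


def molar_concentration(n_molecules: float, volume_um3: float) -> float:
    """Convert a copy number in a cell volume (μm³) to micromolar.

    ``c = n / (N_A · V)`` with 1 μm³ = 1e-15 L; the return value is in μM.
    """
    if n_molecules <= 0 or volume_um3 <= 0:
        raise ContractError("molecule count and volume must be positive")
    litres = volume_um3 * 1e-15
    return n_molecules / (Avogadro * litres) * 1e6


def round_sig(x: float, digits: int = 1) -> float:
    """Round to ``digits`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + digits - 1)


# -- isoelectric point --------------------------------------------------------

# side-chain and termini pKa sets; "emboss" follows the EMBOSS iep defaults,
# "bjellqvist" the classic 2D-gel calibration used by several web calculators
PKA_TABLES: dict[str, dict[str, float]] = {
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98,
        "K": 10.0, "R": 12.0, "Y": 10.0,
    },
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")
_AMINO = set("ACDEFGHIKLMNPQRSTVWY")


def net_charge(sequence: str, pH: float, pka_table: str | dict = "emboss") -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    table = PKA_TABLES[pka_table] if isinstance(pka_table, str) else pka_table
    seq = sequence.upper()
    bad = set(seq) - _AMINO
    if bad:
        raise ContractError(f"unknown residues {sorted(bad)}")
    if not seq:
        raise ContractError("empty sequence")
    z = 1.0 / (1.0 + 10.0 ** (pH - table["Nterm"]))
    z -= 1.0 / (1.0 + 10.0 ** (table["Cterm"] - pH))
    for aa in _POSITIVE:
        z += seq.count(aa) / (1.0 + 10.0 ** (pH - table[aa]))
    for aa in _NEGATIVE:
        z -= seq.count(aa) / (1.0 + 10.0 ** (table[aa] - pH))
    return z


def isoelectric_point(
    sequence: str,
    pka_table: str | dict = "emboss",
    tol: float = 1e-4,
) -> float:
    """pH at which the peptide's net charge vanishes, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so bisection converges; the
    result depends on the chosen pKa set by up to a few tenths of a pH unit.
    """
    lo, hi = 0.0, 14.0
    z_lo = net_charge(sequence, lo, pka_table)
    z_hi = net_charge(sequence, hi, pka_table)
    if z_lo <= 0:
        return lo
    if z_hi >= 0:
        return hi
    for _ in range(200):
        mid = (lo + hi) / 2.0
        z = net_charge(sequence, mid, pka_table)
        if abs(z) < tol:
            return mid
        if z > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# -- G-quadruplex motif scanning ----------------------------------------------


@dataclass(frozen=True)
class G4Hit:
    """One retained quadruplex candidate: four G-tracts of ``g_group`` Gs
    separated by three loops, spanning ``[start, end)`` on the input."""

    start: int
    end: int
    g_group: int
    loops: tuple[int, int, int]
    sequence: str

    @property
    def total_len(self) -> int:
        return self.end - self.start


_NUC = set("ACGTU")


def enumerate_g4_candidates(
    seq: str,
    min_g: int = 2,
    max_len: int = 20,
    min_loop: int = 0,
) -> list[G4Hit]:
    """Exhaustively enumerate every window matching G{g} N* G{g} N* G{g} N* G{g}.

    All placements with tract size ``g >= min_g``, loop lengths at least
    ``min_loop`` and total length at most ``max_len`` are returned, including
    overlapping ones; use :func:`scan_g4` for the collapsed non-overlapping
    set.
    """
    s = seq.upper()
    bad = set(s) - _NUC
    if bad:
        raise ContractError(f"invalid characters {sorted(bad)} in sequence")
    n = len(s)
    is_g = [c == "G" for c in s]

    def tract(p: int, g: int) -> bool:
        return p + g <= n and all(is_g[p : p + g])

    hits = []
    max_g = max_len // 4
    for g in range(min_g, max_g + 1):
        budget = max_len - 4 * g  # total loop length available
        if budget < 3 * min_loop:
            continue
        for start in range(n):
            if not tract(start, g):
                continue
            for l1 in range(min_loop, budget - 2 * min_loop + 1):
                p2 = start + g + l1
                if not tract(p2, g):
                    continue
                for l2 in range(min_loop, budget - l1 - min_loop + 1):
                    p3 = p2 + g + l2
                    if not tract(p3, g):
                        continue
                    for l3 in range(min_loop, budget - l1 - l2 + 1):
                        p4 = p3 + g + l3
                        if not tract(p4, g):
                            continue
                        end = p4 + g
                        hits.append(
                            G4Hit(
                                start=start,
                                end=end,
                                g_group=g,
                                loops=(l1, l2, l3),
                                sequence=s[start:end],
                            )
                        )
    return hits


def scan_g4(
    seq: str,
    min_g: int = 2,
    max_len: int = 20,
    regions: list[tuple[str, int, int]] | None = None,
    min_loop: int = 0,
) -> tuple[list[G4Hit], dict[str, int] | None]:
    """Scan a sequence for G-quadruplex motifs and collapse overlaps.

    Candidates are enumerated exhaustively, then reduced to a non-overlapping
    set by a deterministic greedy rule: prefer the largest G-group, then the
    shortest total length, then the smallest start.  When ``regions`` (name,
    0-based start, half-open end) are given, retained hits are counted per
    region by their start position; regions must not overlap and must lie
    within the sequence.
    """
    candidates = enumerate_g4_candidates(seq, min_g=min_g, max_len=max_len,
                                         min_loop=min_loop)
    candidates.sort(key=lambda h: (-h.g_group, h.total_len, h.start))
    kept: list[G4Hit] = []
    for h in candidates:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)

    counts = None
    if regions is not None:
        ivs = sorted(regions, key=lambda r: r[1])
        for (na, sa, ea), (nb, sb, eb) in zip(ivs, ivs[1:]):
            if sb < ea:
                raise ContractError(f"regions {na!r} and {nb!r} overlap")
        for name, s0, e0 in ivs:
            if s0 < 0 or e0 > len(seq) or s0 >= e0:
                raise ContractError(f"region {name!r} out of bounds")
        counts = {name: 0 for name, _, _ in regions}
        for h in kept:
            for name, s0, e0 in regions:
                if s0 <= h.start < e0:
                    counts[name] += 1
                    break
    return kept, counts
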