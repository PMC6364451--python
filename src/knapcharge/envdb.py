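"""Database of k-neighbourhood environment classes with partial-charge histograms.

For every atom of every reference molecule, the induced subgraphs of its
0..k-neighbourhoods are canonicalised and the atom's partial charge is
appended to the matching isomorphism class.  Each class condenses its
observations into a histogram whose bin width follows the Freedman–Diaconis
rule and whose bin grid is aligned to the class median charge.  Queries match
an atom's shell-k environment and fall back through smaller shells when no
class matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .molgraph import (
    MolecularGraph,
    ValidationError,
    canonical_key,
    charge_to_milli,
    induced_environment,
    milli_to_charge,
)

__all__ = [
    "ChargeHistogram",
    "EnvironmentEntry",
    "EnvironmentDatabase",
    "fd_bin_width",
    "build_histogram",
    "build_database",
    "lookup_environment",
    "save_database",
    "load_database",
]


def fd_bin_width(values: Sequence[float]) -> float:
    """Freedman–Diaconis bin width 2·IQR·n^(−1/3), linear-interpolation quantiles."""
    if len(values) == 0:
        raise ValidationError("fd_bin_width requires a non-empty value list")
    arr = np.asarray(values, dtype=float)
    iqr = float(stats.iqr(arr, interpolation="linear"))
    if iqr == 0.0:
        return 0.0
    return 2.0 * iqr * len(arr) ** (-1.0 / 3.0)


@dataclass
class ChargeHistogram:
    """Binned charge observations for one environment class.

    ``bin_width == 0`` marks the discrete case: one bin per distinct
    observed value.  Otherwise centers sit on a grid of spacing ``bin_width``
    aligned to the 3-decimal-rounded median charge.  ``values`` is ``None``
    for histograms deserialised without raw observations.
    """

    bin_centers: list[float]
    counts: list[int]
    bin_width: float
    values: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.bin_centers) != len(self.counts):
            raise ValidationError("bin_centers and counts length mismatch")
        if not self.bin_centers:
            raise ValidationError("histogram has no bins")
        if any(c <= 0 for c in self.counts):
            raise ValidationError("histogram counts must be positive")
        if any(b >= a for a, b in zip(self.bin_centers[1:], self.bin_centers)):
            raise ValidationError("bin_centers must be strictly increasing")
        if self.values is not None and sum(self.counts) != len(self.values):
            raise ValidationError(
                f"counts sum {sum(self.counts)} != number of values {len(self.values)}"
            )

    @property
    def n_values(self) -> int:
        return len(self.values) if self.values is not None else sum(self.counts)

    def mode(self) -> float:
        """Center of the highest-count bin; ties resolved nearest the median,
        then to the lower charge."""
        best = max(self.counts)
        cands = [c for c, n in zip(self.bin_centers, self.counts) if n == best]
        if len(cands) == 1:
            return cands[0]
        if self.values is not None:
            med = float(np.median(self.values))
        else:  # approximate median from the binned representation
            med = self.approx_median()
        return min(cands, key=lambda c: (abs(c - med), c))

    def approx_median(self) -> float:
        expanded = np.repeat(self.bin_centers, self.counts)
        return float(np.median(expanded))


def build_histogram(values: Sequence[float]) -> ChargeHistogram:
    """Bin 3-decimal charge observations.

    The Freedman–Diaconis width, rounded to the 0.001 e grid, sets the bin
    spacing; the grid is anchored so one center equals the rounded median.
    Values are assigned to the nearest center (boundary ties to the lower
    center) and empty bins are dropped.  When the width rounds below 0.001,
    or the median bin would end up empty (an unpopulated central gap), the
    distribution is treated as discrete: one bin per distinct value.
    """
    if len(values) == 0:
        raise ValidationError("build_histogram requires a non-empty value list")
    millis = [charge_to_milli(v) for v in values]
    vals = [milli_to_charge(m) for m in millis]
    bw = round(fd_bin_width(vals), 3)
    if bw >= 0.001:
        bw_m = int(round(bw * 1000))
        med_m = charge_to_milli(round(float(np.median(vals)), 3))
        counts: dict[int, int] = {}
        for m in millis:
            q, r = divmod(m - med_m, bw_m)
            i = q + 1 if 2 * r > bw_m else q
            counts[i] = counts.get(i, 0) + 1
        if 0 in counts:
            idx = sorted(counts)
            centers = [milli_to_charge(med_m + i * bw_m) for i in idx]
            return ChargeHistogram(centers, [counts[i] for i in idx], bw, vals)
        # median bin empty: fall through to the discrete representation
    uniq: dict[int, int] = {}
    for m in millis:
        uniq[m] = uniq.get(m, 0) + 1
    idx = sorted(uniq)
    return ChargeHistogram(
        [milli_to_charge(m) for m in idx], [uniq[m] for m in idx], 0.0, vals
    )


@dataclass
class EnvironmentEntry:
    """One isomorphism class: its canonical key, shell, histogram and provenance."""

    key: str
    shell: int
    histogram: ChargeHistogram
    n_molecules: int
    sources: list[str] | None = None  # molecule identifier per observed value

    def __post_init__(self) -> None:
        if self.shell < 0:
            raise ValidationError("shell must be >= 0")
        if self.sources is not None and self.histogram.values is not None:
            if len(self.sources) != len(self.histogram.values):
                raise ValidationError("sources and values length mismatch")


@dataclass
class EnvironmentDatabase:
    """Canonical-key → histogram entries for every shell 0..k_max."""

    k_max: int
    alphabet: list[str] = field(default_factory=list)
    entries: dict[int, dict[str, EnvironmentEntry]] = field(default_factory=dict)
    track_sources: bool = False

    @property
    def n_entries(self) -> int:
        return sum(len(d) for d in self.entries.values())

    def get(self, shell: int, key: str) -> EnvironmentEntry | None:
        return self.entries.get(shell, {}).get(key)

    def add_entry(self, entry: EnvironmentEntry) -> None:
        self.entries.setdefault(entry.shell, {})[entry.key] = entry

    def without_molecule(self, identifier: str) -> "EnvironmentDatabase":
        """A copy with every observation contributed by ``identifier`` removed.

        Histograms of touched entries are rebuilt; entries left empty vanish.
        Requires the database to have been built with source tracking.
        """
        if not self.track_sources:
            raise ValidationError(
                "database lacks per-value sources; rebuild with track_sources "
                "(--track-sources) to support leave-one-out"
            )
        out = EnvironmentDatabase(self.k_max, list(self.alphabet), {}, True)
        for shell, by_key in self.entries.items():
            for key, e in by_key.items():
                assert e.sources is not None and e.histogram.values is not None
                if identifier not in e.sources:
                    out.add_entry(e)
                    continue
                kept = [
                    (v, s)
                    for v, s in zip(e.histogram.values, e.sources)
                    if s != identifier
                ]
                if not kept:
                    continue
                vals = [v for v, _ in kept]
                srcs = [s for _, s in kept]
                out.add_entry(
                    EnvironmentEntry(key, shell, build_histogram(vals), len(set(srcs)), srcs)
                )
        return out


def build_database(
    molecules: Sequence[MolecularGraph], k: int, track_sources: bool = False
) -> EnvironmentDatabase:
    """Collect charges of every atom's 0..k-shell environments into histograms."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    raw: dict[tuple[int, str], tuple[list[float], list[str]]] = {}
    alphabet: set[str] = set()
    for mol in molecules:
        if not mol.has_charges:
            raise ValidationError(f"molecule {mol.identifier!r} is missing charges")
        alphabet.update(a.type_label for a in mol.atoms)
        for v in range(1, mol.n_atoms + 1):
            charge = round(mol.atoms[v - 1].charge, 3)  # type: ignore[arg-type]
            for shell in range(k + 1):
                key = canonical_key(induced_environment(mol, v, shell))
                vals, srcs = raw.setdefault((shell, key), ([], []))
                vals.append(charge)
                srcs.append(mol.identifier)
    db = EnvironmentDatabase(k, sorted(alphabet), {}, track_sources)
    for (shell, key), (vals, srcs) in raw.items():
        db.add_entry(
            EnvironmentEntry(
                key,
                shell,
                build_histogram(vals),
                len(set(srcs)),
                srcs if track_sources else None,
            )
        )
    return db


def lookup_environment(
    db: EnvironmentDatabase, molecule: MolecularGraph, v: int, k: int
) -> tuple[EnvironmentEntry, int] | None:
    """Match atom ``v``'s shell-k environment, falling back through k−1, …, 0.

    Returns ``(entry, matched shell)`` or ``None`` when even the bare
    atom-type class is absent.
    """
    if k > db.k_max:
        raise ValidationError(f"k={k} exceeds database k_max={db.k_max}")
    for shell in range(k, -1, -1):
        key = canonical_key(induced_environment(molecule, v, shell))
        entry = db.get(shell, key)
        if entry is not None:
            return entry, shell
    return None


# -- serialisation -------------------------------------------------------


def save_database(db: EnvironmentDatabase, path: str | Path) -> None:
    entries = []
    for shell in sorted(db.entries):
        for key in sorted(db.entries[shell]):
            e = db.entries[shell][key]
            h = e.histogram
            rec = {
                "key": key,
                "shell": shell,
                "bin_width": h.bin_width,
                "bin_centers": h.bin_centers,
                "counts": h.counts,
                "n_values": h.n_values,
                "n_molecules": e.n_molecules,
            }
            if db.track_sources and e.sources is not None:
                rec["sources"] = e.sources
                rec["values"] = h.values
            entries.append(rec)
    obj = {
        "alphabet": db.alphabet,
        "k_max": db.k_max,
        "track_sources": db.track_sources,
        "entries": entries,
    }
    Path(path).write_text(json.dumps(obj, separators=(",", ":")) + "\n")


def load_database(path: str | Path) -> EnvironmentDatabase:
    obj = json.loads(Path(path).read_text())
    try:
        db = EnvironmentDatabase(
            int(obj["k_max"]), list(obj["alphabet"]), {}, bool(obj.get("track_sources", False))
        )
    except (KeyError, TypeError) as e:
        raise ValidationError(f"invalid database schema at /: {e}") from None
    for i, rec in enumerate(obj.get("entries", [])):
        try:
            counts = [int(c) for c in rec["counts"]]
            if sum(counts) != int(rec["n_values"]):
                raise ValidationError(
                    f"invalid database entry at /entries/{i}/counts: "
                    f"sum {sum(counts)} != n_values {rec['n_values']}"
                )
            hist = ChargeHistogram(
                [float(c) for c in rec["bin_centers"]],
                counts,
                float(rec.get("bin_width", 0.0)),
                [float(v) for v in rec["values"]] if "values" in rec else None,
            )
            db.add_entry(
                EnvironmentEntry(
                    rec["key"],
                    int(rec["shell"]),
                    hist,
                    int(rec["n_molecules"]),
                    list(rec["sources"]) if "sources" in rec else None,
                )
            )
        except ValidationError:
            raise
        except (KeyError, TypeError, ValueError) as e:
            raise ValidationError(f"invalid database entry at /entries/{i}: {e}") from None
    return db
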