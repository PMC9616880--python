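"""Staggered master-mix manifests: the quantitative reference ladder.

The panel is split into groups (default: eight groups of nine adaptors) and
each group is carried through a serial ``fold``-fold dilution, giving
relative concentrations fold^0 .. fold^-(n_levels-1) (default: undiluted to
1:128). Equal amounts of each dilution are pooled, so within a level every
adaptor has the same relative concentration; expected read fractions follow
by normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as ckio
from .errors import FormatError, InvalidParameterError

__all__ = ["ManifestEntry", "MixtureManifest", "build_staggered_manifest",
           "read_manifest", "write_manifest"]


@dataclass(frozen=True)
class ManifestEntry:
    captor_id: str
    group: int  # dilution level index, 0 = undiluted
    relative_concentration: float
    expected_fraction: float


@dataclass(frozen=True)
class MixtureManifest:
    entries: tuple[ManifestEntry, ...]

    def __post_init__(self):
        ids = [e.captor_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate captor_id {dup!r} in manifest")
        total = sum(e.expected_fraction for e in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise FormatError(
                f"expected fractions sum to {total:.6g}, not 1")

    @property
    def ids(self) -> list[str]:
        return [e.captor_id for e in self.entries]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([e.expected_fraction for e in self.entries])

    def fraction_of(self, captor_id: str) -> float:
        for e in self.entries:
            if e.captor_id == captor_id:
                return e.expected_fraction
        raise KeyError(captor_id)

    @property
    def dynamic_range(self) -> float:
        conc = [e.relative_concentration for e in self.entries]
        return max(conc) / min(conc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def build_staggered_manifest(captor_ids: list[str], group_size: int = 9,
                             n_levels: int = 8, fold: float = 2.0
                             ) -> MixtureManifest:
    """Assign adaptors (in input order) to dilution levels.

    Level g receives ``group_size`` adaptors at relative concentration
    fold^-g; expected fractions are the normalised concentrations.
    """
    if fold <= 1:
        raise InvalidParameterError("fold must be > 1")
    if group_size < 1 or n_levels < 1:
        raise InvalidParameterError("group_size and n_levels must be >= 1")
    need = group_size * n_levels
    if len(captor_ids) != need:
        raise InvalidParameterError(
            f"need exactly group_size * n_levels = {need} adaptor ids, "
            f"got {len(captor_ids)}")
    conc = np.array([float(fold) ** -(i // group_size) for i in range(need)])
    frac = conc / conc.sum()
    entries = tuple(
        ManifestEntry(captor_id=cid, group=i // group_size,
                      relative_concentration=conc[i], expected_fraction=frac[i])
        for i, cid in enumerate(captor_ids))
    return MixtureManifest(entries)


def write_manifest(manifest: MixtureManifest, path) -> None:
    df = manifest.to_frame()
    ckio.write_tsv(df, path, float_format="%.17g")


def read_manifest(path) -> MixtureManifest:
    df = ckio.read_tsv(path)
    required = {"captor_id", "group", "relative_concentration"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}",
                          path=str(path))
    dups = df.captor_id[df.captor_id.duplicated()]
    if len(dups):
        raise FormatError(f"duplicate captor_id {dups.iloc[0]!r}",
                          path=str(path),
                          line=int(dups.index[0]) + 2)
    if (df.relative_concentration <= 0).any():
        bad = df.index[df.relative_concentration <= 0][0]
        raise FormatError("non-positive relative_concentration",
                          path=str(path), line=int(bad) + 2)
    conc = df.relative_concentration.to_numpy(float)
    frac = conc / conc.sum()
    if "expected_fraction" in df.columns:
        stored = df.expected_fraction.to_numpy(float)
        if np.abs(stored - frac).max() > 1e-9:
            raise FormatError(
                "stored expected_fraction inconsistent with relative "
                "concentrations (normalisation mismatch)", path=str(path))
    entries = tuple(
        ManifestEntry(captor_id=str(r.captor_id), group=int(r.group),
                      relative_concentration=float(r.relative_concentration),
                      expected_fraction=float(f))
        for r, f in zip(df.itertuples(), frac))
    return MixtureManifest(entries)
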