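"""Pore-model k-mer parameter tables.

A k-mer table stores, for every k-mer, the Gaussian baseline of the ionic
current while that k-mer occupies the pore: mean and standard deviation of
the unmodified state and, optionally, of a modified state together with the
mixture weights of the two states.  Two tab-separated dialects are
supported: the ONT pore-model dialect (columns ``kmer``, ``level_mean``,
``level_stdv``) and an extended dialect that carries the modified-state
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from squigseg.errors import FormatError, ValidationError

_VALID_BASES = frozenset("ACGT")

# IUPAC D = A/G/T, R = A/G (purine), H = A/C/T
_DRACH_SETS = (
    frozenset("AGT"),
    frozenset("AG"),
    frozenset("A"),
    frozenset("C"),
    frozenset("ACT"),
)


def normalize_kmer(kmer: str) -> str:
    """Uppercase a k-mer and map RNA U to DNA T."""
    return kmer.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class KmerParams:
    """Current baseline parameters of one k-mer.

    ``mu_un``/``sigma_un`` describe the unmodified state, ``mu_mod``/
    ``sigma_mod`` the modified state (present only when ``mod_enabled``),
    and ``omega_un``/``omega_mod`` are the mixture weights of the two
    states.  All current values are in pA.
    """

    kmer: str
    mu_un: float
    sigma_un: float
    mu_mod: float | None = None
    sigma_mod: float | None = None
    omega_un: float = 1.0
    omega_mod: float = 0.0
    mod_enabled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "kmer", normalize_kmer(self.kmer))
        if not set(self.kmer) <= _VALID_BASES:
            raise ValidationError(f"k-mer {self.kmer!r} contains non-ACGTU symbols")
        if self.sigma_un <= 0:
            raise ValidationError(f"{self.kmer}: sigma_un must be > 0")
        if self.mod_enabled:
            if self.mu_mod is None or self.sigma_mod is None:
                raise ValidationError(f"{self.kmer}: modified state enabled but parameters absent")
            if self.sigma_mod <= 0:
                raise ValidationError(f"{self.kmer}: sigma_mod must be > 0")
            if abs(self.omega_un + self.omega_mod - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.kmer}: omega_un + omega_mod = "
                    f"{self.omega_un + self.omega_mod} != 1"
                )
        else:
            if abs(self.omega_un - 1.0) > 1e-9:
                raise ValidationError(f"{self.kmer}: omega_un must be 1 when mod is disabled")


@dataclass
class KmerTable:
    """Mapping of k-mers to :class:`KmerParams`, all of one length ``k``."""

    k: int
    entries: dict[str, KmerParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kmer in self.entries:
            if len(kmer) != self.k:
                raise ValidationError(
                    f"k-mer {kmer!r} has length {len(kmer)}, table k = {self.k}"
                )

    def lookup(self, kmer: str) -> KmerParams:
        key = normalize_kmer(kmer)
        try:
            return self.entries[key]
        except KeyError:
            raise ValidationError(f"k-mer {key!r} not present in table") from None

    def __contains__(self, kmer: str) -> bool:
        return normalize_kmer(kmer) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, params: KmerParams) -> None:
        if len(params.kmer) != self.k:
            raise ValidationError(
                f"k-mer {params.kmer!r} has length {len(params.kmer)}, table k = {self.k}"
            )
        self.entries[params.kmer] = params

    def kmers(self) -> list[str]:
        return sorted(self.entries)

    def equals(self, other: "KmerTable", decimals: int = 6) -> bool:
        """Field-for-field equality with floats compared to ``decimals``."""
        if self.k != other.k or set(self.entries) != set(other.entries):
            return False

        def r(x: float | None) -> float | None:
            return None if x is None else round(x, decimals)

        for kmer, a in self.entries.items():
            b = other.entries[kmer]
            if a.mod_enabled != b.mod_enabled:
                return False
            fields = (
                (a.mu_un, b.mu_un),
                (a.sigma_un, b.sigma_un),
                (a.mu_mod, b.mu_mod),
                (a.sigma_mod, b.sigma_mod),
                (a.omega_un, b.omega_un),
                (a.omega_mod, b.omega_mod),
            )
            if any(r(x) != r(y) for x, y in fields):
                return False
        return True


def load_ont_table(path: str | Path) -> KmerTable:
    """Load an ONT pore-model TSV (columns kmer / level_mean / level_stdv).

    Extra columns are ignored; all entries come back unmodified-only with
    ``omega_un = 1``.  U is normalized to T.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("kmer", "level_mean", "level_stdv"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    kmers = [normalize_kmer(s) for s in df["kmer"].astype(str)]
    lengths = {len(s) for s in kmers}
    if len(lengths) != 1:
        raise ValidationError(f"{path}: inconsistent k-mer lengths {sorted(lengths)}")
    if len(set(kmers)) != len(kmers):
        raise ValidationError(f"{path}: duplicate k-mers")
    k = lengths.pop()
    entries = {
        kmer: KmerParams(kmer=kmer, mu_un=float(m), sigma_un=float(s))
        for kmer, m, s in zip(kmers, df["level_mean"], df["level_stdv"])
    }
    return KmerTable(k=k, entries=entries)


_EXT_COLUMNS = [
    "kmer",
    "mu_un",
    "sigma_un",
    "mu_mod",
    "sigma_mod",
    "omega_un",
    "omega_mod",
    "mod_enabled",
]


def save_table(table: KmerTable, path: str | Path) -> None:
    """Write a table in the extended dialect.

    Modified-state columns of unmodified-only rows are written as ``NA``.
    """
    rows = []
    for kmer in table.kmers():
        p = table.entries[kmer]
        rows.append(
            {
                "kmer": kmer,
                "mu_un": f"{p.mu_un:.6f}",
                "sigma_un": f"{p.sigma_un:.6f}",
                "mu_mod": f"{p.mu_mod:.6f}" if p.mod_enabled else "NA",
                "sigma_mod": f"{p.sigma_mod:.6f}" if p.mod_enabled else "NA",
                "omega_un": f"{p.omega_un:.6f}",
                "omega_mod": f"{p.omega_mod:.6f}",
                "mod_enabled": int(p.mod_enabled),
            }
        )
    try:
        pd.DataFrame(rows, columns=_EXT_COLUMNS).to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise FormatError(f"cannot write table to {path}: {exc}") from exc


def load_table(path: str | Path) -> KmerTable:
    """Load an extended-dialect table written by :func:`save_table`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except OSError as exc:
        raise FormatError(f"cannot read table from {path}: {exc}") from exc
    for col in _EXT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    kmers = [normalize_kmer(s) for s in df["kmer"].astype(str)]
    lengths = {len(s) for s in kmers}
    if len(lengths) != 1:
        raise ValidationError(f"{path}: inconsistent k-mer lengths {sorted(lengths)}")
    entries: dict[str, KmerParams] = {}
    for kmer, row in zip(kmers, df.itertuples(index=False)):
        mod_enabled = bool(int(row.mod_enabled))
        entries[kmer] = KmerParams(
            kmer=kmer,
            mu_un=float(row.mu_un),
            sigma_un=float(row.sigma_un),
            mu_mod=float(row.mu_mod) if mod_enabled else None,
            sigma_mod=float(row.sigma_mod) if mod_enabled else None,
            omega_un=float(row.omega_un),
            omega_mod=float(row.omega_mod) if not math.isnan(row.omega_mod) else 0.0,
            mod_enabled=mod_enabled,
        )
    return KmerTable(k=lengths.pop(), entries=entries)


def is_drach(kmer: str) -> bool:
    """True iff the 5-mer matches the m6A DRACH motif (D-R-A-C-H).

    D is A/G/T (U written as T), R is a purine (A/G), H is A/C/T; the
    central A is the potentially methylated base.
    """
    kmer = normalize_kmer(kmer)
    if len(kmer) != 5:
        raise ValidationError(f"DRACH test requires a 5-mer, got {kmer!r}")
    if not set(kmer) <= _VALID_BASES:
        raise ValidationError(f"k-mer {kmer!r} contains non-ACGTU symbols")
    return all(base in allowed for base, allowed in zip(kmer, _DRACH_SETS))


def with_modification(
    table: KmerTable,
    delta: float = 8.0,
    sigma_mod: float | None = None,
    omega_mod: float = 0.3,
    motif: str = "drach",
) -> KmerTable:
    """Return a copy of ``table`` with modified-state parameters added.

    The modified baseline of every motif-matching k-mer is offset by
    ``delta`` pA from the unmodified mean.  Used to build generating tables
    for simulation and perturbed starting tables for re-estimation tests.
    """
    new = KmerTable(k=table.k, entries=dict(table.entries))
    for kmer, p in table.entries.items():
        if motif == "drach" and table.k == 5 and not is_drach(kmer):
            continue
        new.entries[kmer] = replace(
            p,
            mu_mod=p.mu_un + delta,
            sigma_mod=sigma_mod if sigma_mod is not None else p.sigma_un,
            omega_un=1.0 - omega_mod,
            omega_mod=omega_mod,
            mod_enabled=True,
        )
    return new
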