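"""Reflection-list text formats.

Two dialects:

* ``shelx`` — fixed-width records: three 4-character integer fields
  (h, k, l) followed by two 8-character reals (amplitude, phase in
  radians), in the spirit of SHELX HKLF files;
* ``tsv`` — free-format tab-separated with a ``# h k l amplitude phase``
  header line.

Both round-trip bit-exactly through :func:`read_hkl` at the written
precision.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .diffraction import ReflectionSet, d_spacings
from .errors import DomainError

__all__ = ["write_hkl", "read_hkl"]

_DIALECTS = ("shelx", "tsv")


def write_hkl(refs: ReflectionSet, destination, dialect: str = "shelx") -> None:
    if dialect not in _DIALECTS:
        raise DomainError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    lines = []
    amp = refs.amplitude if len(refs.amplitude) else np.zeros(len(refs))
    pha = refs.phase if len(refs.phase) else np.zeros(len(refs))
    if dialect == "tsv":
        lines.append("# h\tk\tl\tamplitude\tphase")
        for (h, k, l), a, p in zip(refs.hkl, amp, pha):
            lines.append(f"{h}\t{k}\t{l}\t{a:.6f}\t{p:.6f}")
    else:
        lines.append("!   h   k   l amplitude    phase")
        for (h, k, l), a, p in zip(refs.hkl, amp, pha):
            if not (-999 <= h <= 9999 and -999 <= k <= 9999 and -999 <= l <= 9999):
                raise DomainError(f"index ({h},{k},{l}) overflows 4-character field")
            if not 0 <= a < 1e7:
                raise DomainError(f"amplitude {a} overflows fixed-width field")
            lines.append(f"{h:4d}{k:4d}{l:4d}{a:10.3f}{p:8.4f}")
    Path(destination).write_text("\n".join(lines) + "\n")


def read_hkl(source, vectors: np.ndarray | None = None) -> ReflectionSet:
    """Read either dialect back (auto-detected).

    d-spacings are recomputed when lattice vectors are supplied, else NaN.
    """
    hkl, amp, pha = [], [], []
    for line in Path(source).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith(("#", "!")):
            continue
        if "\t" in line:
            h, k, l, a, p = line.split("\t")
        else:
            h, k, l = line[0:4], line[4:8], line[8:12]
            a, p = line[12:22], line[22:30]
        hkl.append((int(h), int(k), int(l)))
        amp.append(float(a))
        pha.append(float(p))
    hkl_arr = np.asarray(hkl, dtype=int).reshape(-1, 3)
    d = (
        d_spacings(vectors, hkl_arr)
        if vectors is not None and len(hkl_arr)
        else np.full(len(hkl_arr), np.nan)
    )
    return ReflectionSet(
        hkl=hkl_arr,
        d=d,
        amplitude=np.asarray(amp),
        phase=np.asarray(pha),
    )
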