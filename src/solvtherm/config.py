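"""Plain-text (key = value) serialization of fitted model parameters.

Sections name the phase and variant, e.g.::

    [cyclohexane/3-par]
    c_mu = 1.8516
    c_V = -0.14692
    c_q = 0.0
    d = -1.0842

    [pka]
    a = 0.6
    b = -160.0
"""

from __future__ import annotations

import configparser
from typing import Iterable, Optional

from .observables import PkaModelParams
from .state_model import CorrectionParams, SolventPhase

__all__ = ["write_params", "read_params"]


def write_params(
    path: str,
    corrections: Iterable[CorrectionParams] = (),
    pka: Optional[PkaModelParams] = None,
) -> None:
    cp = configparser.ConfigParser()
    for p in corrections:
        section = f"{p.phase.name}/{p.variant}"
        cp[section] = {
            "c_mu": repr(p.c_mu),
            "c_V": repr(p.c_V),
            "c_q": repr(p.c_q),
            "d": repr(p.d),
        }
    if pka is not None:
        cp["pka"] = {"a": repr(pka.a), "b": repr(pka.b)}
    with open(path, "w", encoding="utf-8") as fh:
        cp.write(fh)


def read_params(path: str) -> tuple[dict[tuple[str, str], CorrectionParams], Optional[PkaModelParams]]:
    """Read a parameter config; returns ({(phase, variant): params}, pka)."""
    cp = configparser.ConfigParser()
    with open(path, "r", encoding="utf-8") as fh:
        cp.read_file(fh)
    corrections: dict[tuple[str, str], CorrectionParams] = {}
    pka = None
    for section in cp.sections():
        if section == "pka":
            pka = PkaModelParams(a=cp.getfloat(section, "a"), b=cp.getfloat(section, "b"))
            continue
        if "/" not in section:
            raise ValueError(f"section {section!r}: expected '<phase>/<variant>' or 'pka'")
        phase_name, variant = section.split("/", 1)
        corrections[(phase_name, variant)] = CorrectionParams(
            variant=variant,
            phase=SolventPhase(phase_name),
            c_mu=cp.getfloat(section, "c_mu", fallback=1.0),
            c_V=cp.getfloat(section, "c_V", fallback=0.0),
            c_q=cp.getfloat(section, "c_q", fallback=0.0),
            d=cp.getfloat(section, "d", fallback=0.0),
        )
    return corrections, pka
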