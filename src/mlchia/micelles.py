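"""Arithmetic of mixed bile-salt/lecithin micellar mobile phases.

A micellar liquid chromatography (MLC) mobile phase is a surfactant
solution above its critical micellar concentration (CMC).  For a mixed
system the micellar concentration entering the retention model is

    C_M = C_total - CMC_mix

where ``C_total`` is the total bile-salt concentration and ``CMC_mix``
the mixture CMC, taken as the arithmetic mean of the component CMCs.
This module keeps the composition bookkeeping (stock preparation,
dilution-series design) in mM and exposes ``C_M`` in M, the unit used by
the retention model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "SurfactantComponent",
    "MicellarMixture",
    "DilutionPlan",
    "MicellarSystemError",
    "total_concentration",
    "mixture_cmc",
    "micellar_concentration",
    "dilution_fractions",
    "load_micellar_system",
    "paper_micellar_system",
]


class MicellarSystemError(ValueError):
    """Invalid micellar-system configuration or arithmetic."""


@dataclass(frozen=True)
class SurfactantComponent:
    """One surfactant in the mixture.

    Parameters
    ----------
    name
        Short label, e.g. ``"NaTC"`` for sodium taurocholate.
    concentration
        Molar concentration in the mixture, mM.
    cmc
        CMC of the pure component in 0.15 M NaCl, M.  ``None`` when the
        value is not needed (e.g. for dilution bookkeeping only).
    """

    name: str
    concentration: float
    cmc: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise MicellarSystemError("component name must be non-empty")
        if self.concentration < 0:
            raise MicellarSystemError(
                f"component {self.name!r}: concentration must be >= 0 mM"
            )
        if self.cmc is not None and self.cmc <= 0:
            raise MicellarSystemError(f"component {self.name!r}: cmc must be > 0 M")


@dataclass(frozen=True)
class MicellarMixture:
    """A mixed micellar mobile phase.

    ``components`` are the bile salts; lecithin is tracked separately and
    does not count towards the bile-salt total used for C_M (the stated
    stock total refers to the bile salts alone).
    """

    components: tuple[SurfactantComponent, ...]
    lecithin_concentration: float = 0.0
    salt_background: float | None = None
    buffer_ph: float | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise MicellarSystemError("mixture needs at least one component")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise MicellarSystemError(f"duplicate component names in {names}")
        if self.lecithin_concentration < 0:
            raise MicellarSystemError("lecithin concentration must be >= 0 mM")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def total_bile_salt_concentration(self) -> float:
        """Sum of bile-salt component concentrations, mM."""
        return total_concentration(self)

    @property
    def mixture_cmc(self) -> float:
        """Mixture CMC in M (mean of component CMCs)."""
        return mixture_cmc(self.components)


@dataclass(frozen=True)
class DilutionPlan:
    """Volume fractions of stock needed to hit each target concentration."""

    stock_concentration: float
    diluent_concentration: float
    targets: tuple[float, ...]
    fractions: tuple[float, ...] = field(default=())

    def to_csv(self, path: str | Path) -> None:
        lines = ["target_mM,stock_fraction"]
        lines += [f"{t:g},{f:.10g}" for t, f in zip(self.targets, self.fractions)]
        Path(path).write_text("\n".join(lines) + "\n")


def total_concentration(mixture: MicellarMixture) -> float:
    """Total bile-salt concentration of the mixture, mM.

    Lecithin is excluded: the phase is described by its bile-salt total
    (e.g. the 17 mM stock), with the 0.75 mM phosphatidylcholine listed
    separately.
    """
    if not mixture.components:
        raise MicellarSystemError("mixture has no components")
    return sum(c.concentration for c in mixture.components)


def mixture_cmc(components: Sequence[SurfactantComponent]) -> float:
    """Mixture CMC as the unweighted mean of the component CMCs, M.

    For the six physiological bile salts this gives 0.0046 M.  A
    mole-fraction-weighted mean does not reproduce that value, so the
    unweighted mean is the defined behaviour.
    """
    if not components:
        raise MicellarSystemError("no components given")
    missing = [c.name for c in components if c.cmc is None]
    if missing:
        raise MicellarSystemError(f"components missing a CMC: {', '.join(missing)}")
    return sum(c.cmc for c in components) / len(components)  # type: ignore[misc]


def micellar_concentration(
    total: float, cmc: float, *, monomer_background: float | None = None
) -> float:
    """Micellar (micelle-bound surfactant) concentration C_M, M.

    Default is ``total - cmc``.  If ``monomer_background`` is given (M),
    that value is subtracted instead — the constant-monomer view in which
    the diluting mixture concentration (2 mM) is the monomer pool.
    """
    sub = cmc if monomer_background is None else monomer_background
    if sub < 0 or total < 0:
        raise MicellarSystemError("concentrations must be non-negative")
    if total < sub:
        raise MicellarSystemError(
            f"total {total} M below CMC {sub} M; no micellar phase"
        )
    return total - sub


def dilution_fractions(
    stock: float, diluent: float, targets: Sequence[float]
) -> DilutionPlan:
    """Stock volume fraction for each target: (target - diluent)/(stock - diluent).

    Targets must lie in the half-open interval (diluent, stock]: pure
    diluent is below the CMC and is not a usable micellar level.
    """
    if diluent >= stock:
        raise MicellarSystemError(
            f"diluent {diluent} mM must be below stock {stock} mM"
        )
    bad = [t for t in targets if not (diluent < t <= stock)]
    if bad:
        raise MicellarSystemError(
            f"targets outside ({diluent}, {stock}] mM: {bad}"
        )
    fractions = tuple((t - diluent) / (stock - diluent) for t in targets)
    return DilutionPlan(stock, diluent, tuple(targets), fractions)


def load_micellar_system(path: str | Path) -> MicellarMixture:
    """Read a micellar-system description from a YAML config file.

    Schema::

        components: [{name, conc_mM, cmc_M}, ...]
        lecithin_mM: float   # optional
        nacl_M: float        # optional
        ph: float            # optional
    """
    raw = yaml.safe_load(Path(path).read_text())
    return _mixture_from_dict(raw, source=str(path))


def _mixture_from_dict(raw: dict, source: str = "<config>") -> MicellarMixture:
    if not isinstance(raw, dict) or "components" not in raw:
        raise MicellarSystemError(f"{source}: expected a mapping with 'components'")
    known = {"components", "lecithin_mM", "nacl_M", "ph"}
    unknown = set(raw) - known
    if unknown:
        raise MicellarSystemError(
            f"{source}: unknown keys {sorted(unknown)}; expected {sorted(known)}"
        )
    comps = []
    for entry in raw["components"]:
        extra = set(entry) - {"name", "conc_mM", "cmc_M"}
        if extra:
            raise MicellarSystemError(
                f"{source}: unknown component keys {sorted(extra)}"
            )
        comps.append(
            SurfactantComponent(
                name=entry["name"],
                concentration=float(entry["conc_mM"]),
                cmc=float(entry["cmc_M"]) if "cmc_M" in entry else None,
            )
        )
    return MicellarMixture(
        components=tuple(comps),
        lecithin_concentration=float(raw.get("lecithin_mM", 0.0)),
        salt_background=raw.get("nacl_M"),
        buffer_ph=raw.get("ph"),
    )


def paper_micellar_system() -> MicellarMixture:
    """The bundled physiological six-bile-salt + lecithin system."""
    ref = resources.files("mlchia.data") / "micellar_system_paper.yaml"
    return _mixture_from_dict(yaml.safe_load(ref.read_text()), source=str(ref))
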