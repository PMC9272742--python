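"""Species, regions, reactions, and the species-overlap rule.

A species (say calcium) may be declared several times in one model — once
per cell — as long as the declared geometric domains do not overlap.  This
is what lets a cell object carry its full kinetics and still be reused in a
larger model.  Overlap is checked on declaration and is an error naming the
species and both offending regions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConflictError


@dataclass
class Region:
    """Geometric domain a species can live on.

    kind 'intracellular_1d': ``geometry`` is ``(DiscretizedCell, (section ids...))``;
    kind 'intracellular_3d': ``geometry`` is a VoxelGrid;
    kind 'extracellular':    ``geometry`` is an ECSGrid;
    kind 'point':            a single well-mixed location (geometry None).
    """

    kind: str
    geometry: object = None
    name: str | None = None

    def __post_init__(self):
        if self.kind not in ("intracellular_1d", "intracellular_3d",
                             "extracellular", "point"):
            raise ValueError(f"unknown region kind {self.kind!r}")

    def overlaps(self, other: "Region") -> bool:
        if self.kind != other.kind:
            return False
        if self.kind == "point":
            return self is other
        if self.kind == "intracellular_1d":
            cell_a, secs_a = self.geometry
            cell_b, secs_b = other.geometry
            return cell_a is cell_b and bool(set(secs_a) & set(secs_b))
        return self.geometry is other.geometry


@dataclass
class Species:
    """A chemical species bound to one or more regions."""

    name: str
    regions: tuple[Region, ...]
    d: float = 0.0  # diffusion coefficient, um^2/ms
    z: int = 0  # valence
    initial: float = 0.0  # mM
    values: dict[int, np.ndarray] = field(default_factory=dict)  # region idx -> nodes

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("diffusion coefficient must be >= 0")


@dataclass
class Reaction:
    """reactants -> products with a rate law.

    ``rate_f``/``rate_b`` are either numeric mass-action rate constants
    (``mass_action=True``) or sympy-parseable rate expressions in species
    names (forward only; put the full net rate in ``rate_f``).
    """

    reactants: dict[str, int]
    products: dict[str, int]
    rate_f: object
    rate_b: object = None
    mass_action: bool = True
    name: str | None = None


_registration_hooks: list = []


def on_first_species(hook) -> None:
    """Register a callback run when any model declares its first species
    (used by the state-archive extension registration)."""
    _registration_hooks.append(hook)


class RxdModel:
    """Registry of species and reactions plus the overlap rule."""

    def __init__(self):
        self.species: list[Species] = []
        self.reactions: list[Reaction] = []

    def declare_species(self, name: str, regions, d: float = 0.0, z: int = 0,
                        initial: float = 0.0) -> Species:
        """Register a species; reject overlap with a same-name species."""
        if isinstance(regions, Region):
            regions = (regions,)
        regions = tuple(regions)
        for existing in self.species:
            if existing.name != name:
                continue
            for ra, rb in itertools.product(existing.regions, regions):
                if ra.overlaps(rb):
                    raise ConflictError(
                        f"species {name!r} already covers an overlapping domain "
                        f"(existing region {ra.name or ra.kind!r}, "
                        f"new region {rb.name or rb.kind!r})")
        sp = Species(name=name, regions=regions, d=d, z=z, initial=initial)
        for ri, region in enumerate(regions):
            sp.values[ri] = np.full(_region_size(region), float(initial))
        first = not any(True for _ in self.species)
        self.species.append(sp)
        if first:
            for hook in _registration_hooks:
                hook(self)
        return sp

    def add_reaction(self, reaction: Reaction) -> Reaction:
        names = set(reaction.reactants) | set(reaction.products)
        declared = {sp.name for sp in self.species}
        missing = sorted(names - declared)
        if missing:
            raise KeyError(f"reaction references undeclared species {missing}")
        self.reactions.append(reaction)
        return reaction

    def step(self, dt: float, v: float = 0.0) -> None:
        """One operator-split step: reactions first, then diffusion.

        Reactions are applied at every location (point models have one);
        diffusing species on 1D tree regions are then advanced implicitly.
        3D grids are driven directly through dgadi_step/ecs_step.
        """
        from .diffusion1d import diffuse1d_step
        from .reactions import react_step

        if self.reactions:
            sizes = {sum(len(a) for a in sp.values.values())
                     for sp in self.species}
            if len(sizes) != 1:
                raise ValueError(
                    "reaction stepping requires all species on a common layout")
            conc = np.stack([np.concatenate([sp.values[ri]
                                             for ri in sorted(sp.values)])
                             for sp in self.species])
            conc = react_step(conc, self._kernel(), dt, v=v)
            for row, sp in zip(conc, self.species):
                offset = 0
                for ri in sorted(sp.values):
                    n = len(sp.values[ri])
                    sp.values[ri] = row[offset:offset + n].copy()
                    offset += n
        for sp in self.species:
            if sp.d <= 0:
                continue
            for ri, region in enumerate(sp.regions):
                if region.kind != "intracellular_1d":
                    continue
                cell = region.geometry[0]
                if len(sp.values[ri]) != cell.n:
                    raise NotImplementedError(
                        "1D diffusion requires the region to span the cell")
                sp.values[ri] = diffuse1d_step(sp.values[ri], cell, sp.d, dt)

    def _kernel(self):
        from .reactions import compile_reactions

        names = tuple(sp.name for sp in self.species)
        key = (names, len(self.reactions))
        cached = getattr(self, "_kern_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        kern = compile_reactions(self.reactions, names)
        self._kern_cache = (key, kern)
        return kern

    def species_named(self, name: str) -> Species:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(f"no species named {name!r}")


def _region_size(region: Region) -> int:
    if region.kind == "point":
        return 1
    if region.kind == "intracellular_1d":
        cell = region.geometry[0]
        secs = region.geometry[1]
        total = 0
        for sec in secs:
            total += cell.section_ranges[sec][1]
        return total
    grid = region.geometry
    if hasattr(grid, "n_active"):
        return grid.n_active
    return int(np.prod(grid.shape))
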