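"""Model specification: effects, decay parameters, and constraints.

An ERGM is written as Pr(X = x) ∝ exp(Σ_A θ_A z_A(x)) over a fixed node
set; each :class:`EffectSpec` names one configuration statistic z_A.
Alternating (geometrically weighted) effects carry a decay λ > 1,
defaulting to 2, the common modelling practice; λ is per-effect because
published models override it selectively (e.g. alternating k-out-stars
at λ = 4.5 with the triangle terms at λ = 3).  The normalizing constant
is never represented anywhere: all inference is MCMC-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["EffectSpec", "ModelSpec", "EFFECT_INFO", "DEFAULT_LAMBDA",
           "parse_model_file", "write_model_file"]

DEFAULT_LAMBDA = 2.0

#: name -> (directedness, alternating?, attribute kind)
#: directedness: True directed-only, False undirected-only, None either.
#: attribute kind: None, "binary" or "categorical".
EFFECT_INFO: dict[str, tuple[bool | None, bool, str | None]] = {
    "Edge": (False, False, None),
    "Arc": (True, False, None),
    "Sink": (True, False, None),
    "Source": (True, False, None),
    "Reciprocity": (True, False, None),
    "Loop": (True, False, None),
    "AS": (False, True, None),
    "AltInStars": (True, True, None),
    "AltOutStars": (True, True, None),
    "A2P": (False, True, None),
    "AltTwoPathsT": (True, True, None),
    "AT": (False, True, None),
    "AltKTrianglesT": (True, True, None),
    "AltKTrianglesC": (True, True, None),
    "Sender": (True, False, "binary"),
    "Receiver": (True, False, "binary"),
    "Interaction": (True, False, "binary"),
    "Match": (None, False, "categorical"),
}

_ALIASES = {"Matching": "Match"}

#: Effects whose statistic is the tie count: one per model at most, and
#: the one held fixed under a fixed-density constraint.
DENSITY_EFFECTS = ("Arc", "Edge")


@dataclass(frozen=True)
class EffectSpec:
    """One configuration statistic in a model.

    ``lam`` is the decay λ of an alternating statistic (required > 1,
    present iff the effect is alternating); ``attribute`` names the node
    attribute of Sender/Receiver/Interaction/Match effects.
    """

    name: str
    lam: float | None = None
    attribute: str | None = None

    def __post_init__(self):
        name = _ALIASES.get(self.name, self.name)
        object.__setattr__(self, "name", name)
        if name not in EFFECT_INFO:
            raise ValueError(f"unknown effect {name!r}")
        _, alternating, attr_kind = EFFECT_INFO[name]
        if alternating:
            lam = DEFAULT_LAMBDA if self.lam is None else float(self.lam)
            if lam <= 1.0:
                raise ValueError(f"{name}: lambda must be > 1, got {lam}")
            object.__setattr__(self, "lam", lam)
        elif self.lam is not None:
            raise ValueError(f"{name} takes no lambda")
        if attr_kind is None:
            if self.attribute is not None:
                raise ValueError(f"{name} takes no attribute")
        elif self.attribute is None:
            raise ValueError(f"{name} requires an attribute name")

    @property
    def directed_only(self):
        return EFFECT_INFO[self.name][0]

    @property
    def alternating(self) -> bool:
        return EFFECT_INFO[self.name][1]

    @property
    def attr_kind(self) -> str | None:
        return EFFECT_INFO[self.name][2]

    @property
    def key(self) -> tuple[str, str | None]:
        return (self.name, self.attribute)

    @property
    def label(self) -> str:
        """Human-readable name used in tables and TSV output."""
        parts = [self.name]
        if self.attribute is not None:
            parts.append(self.attribute)
        if self.alternating and self.lam != DEFAULT_LAMBDA:
            parts.append(f"(lambda={self.lam:g})")
        return " ".join(parts)

    def check_compatible(self, directed: bool) -> None:
        d = self.directed_only
        if d is True and not directed:
            raise ValueError(f"effect {self.name} requires a directed network")
        if d is False and directed:
            raise ValueError(f"effect {self.name} requires an undirected network")


@dataclass
class ModelSpec:
    """An ordered effect list plus sampling constraints."""

    effects: list[EffectSpec]
    forbid_reciprocity: bool = False
    allow_loops: bool = False
    fixed_density: bool = False

    def __post_init__(self):
        self.effects = [e if isinstance(e, EffectSpec) else EffectSpec(*e)
                        for e in self.effects]
        keys = [e.key for e in self.effects]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (effect, attribute) pair in model")

    @property
    def n_effects(self) -> int:
        return len(self.effects)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.effects]

    def check_compatible(self, net) -> None:
        for e in self.effects:
            e.check_compatible(net.directed)
        if self.forbid_reciprocity and not net.directed:
            raise ValueError("forbid_reciprocity only applies to directed networks")
        if self.allow_loops and not net.allow_loops:
            raise ValueError("model allows loops but network forbids them")

    def density_effect_index(self) -> int | None:
        for k, e in enumerate(self.effects):
            if e.name in DENSITY_EFFECTS:
                return k
        return None

    def with_lambdas(self, lam_by_effect: dict[str, float]) -> "ModelSpec":
        """Return a copy with λ overridden for the named effects."""
        effects = [replace(e, lam=lam_by_effect[e.name])
                   if e.name in lam_by_effect else e
                   for e in self.effects]
        return ModelSpec(effects, self.forbid_reciprocity,
                         self.allow_loops, self.fixed_density)


# ---------------------------------------------------------------------
# Line-oriented model files:  "EffectName [lambda=x] [attr=name]"
# entries plus "constraint <flag>" lines.
# ---------------------------------------------------------------------

_CONSTRAINTS = ("forbid_reciprocity", "allow_loops", "fixed_density")


def parse_model_file(path) -> ModelSpec:
    effects: list[EffectSpec] = []
    flags = dict.fromkeys(_CONSTRAINTS, False)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if tokens[0] == "constraint":
                if len(tokens) != 2 or tokens[1] not in _CONSTRAINTS:
                    raise ValueError(f"line {lineno}: unknown constraint {line!r}")
                flags[tokens[1]] = True
                continue
            name, lam, attr = tokens[0], None, None
            for tok in tokens[1:]:
                if "=" not in tok:
                    raise ValueError(f"line {lineno}: malformed option {tok!r}")
                key, value = tok.split("=", 1)
                if key == "lambda":
                    lam = float(value)
                elif key == "attr":
                    attr = value
                else:
                    raise ValueError(f"line {lineno}: unknown option {key!r}")
            try:
                effects.append(EffectSpec(name, lam=lam, attribute=attr))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return ModelSpec(effects, **flags)


def write_model_file(model: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        for e in model.effects:
            parts = [e.name]
            if e.alternating:
                parts.append(f"lambda={e.lam:g}")
            if e.attribute is not None:
                parts.append(f"attr={e.attribute}")
            fh.write(" ".join(parts) + "\n")
        for flag in _CONSTRAINTS:
            if getattr(model, flag):
                fh.write(f"constraint {flag}\n")
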