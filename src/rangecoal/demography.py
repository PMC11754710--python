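"""Demographic models as typed, time-ordered event schedules.

A model is a set of sampled demes plus backward-in-time events: lineage
merges (dichotomous splits viewed backwards), admixture foundings (hybrid
origins, where the hybrid's lineages are redistributed to two parents
with proportion alpha), and instantaneous size changes. Migration is
specified as per-generation backward rates between pairs of demes and is
active only while both demes are extant.

Every hybrid founding carries a post-founding bottleneck: the hybrid
deme spends its first 50 generations at 0.5% of its present size,
encoded as an ordinary size-change pair so the simulation engine needs
no bespoke bottleneck logic.

The catalogue covers three 3-deme and eight 4-deme named specifications
(two divergence-order submodels each for the dichotomous 4-deme models
with and without focal gene flow), contrasting dichotomous speciation of
*Ph. gallicum* from *Ph. nigrum* against hybrid-origin scenarios
involving the *Ph. spicatum* lineages.

Numeric fields may be expressions over parameter names (e.g.
``"0.005 * N_Pgal"`` or ``"max(THYB_GAL - 50, 0)"``), resolved when a
concrete parameter vector is bound.
"""

from __future__ import annotations

import ast
import json
import operator
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "DemeSpec",
    "MergeEvent",
    "AdmixtureEvent",
    "SizeChangeEvent",
    "MigrationEpoch",
    "ParameterSpec",
    "DemographicModel",
    "MODEL_NAMES",
    "build_model",
    "model_catalogue",
    "validate_event_order",
    "eval_expr",
]

BOTTLENECK_FRACTION = 0.005
BOTTLENECK_GENERATIONS = 50.0
TDIV_ANC_RANGE = (42_000.0, 139_000.0)

# default search ranges by parameter kind
SIZE_RANGE = (1e2, 2e5)  # diploid individuals, log scale
MIG_RANGE = (1e-8, 1e-2)  # backward rate / generation / lineage, log scale
ALPHA_RANGE = (0.01, 0.99)  # admixture proportion, linear
TIME_RANGE = (100.0, 139_000.0)  # generations, linear

# haploid sample sizes after downsampling (4 alleles x sampling sites)
SAMPLES_3DEME = {"Pgal": 12, "Pnig": 16, "Pspi": 32}
SAMPLES_4DEME = {"Pgal": 12, "Pnig": 16, "PspE": 24, "PspW": 8}


# ---------------------------------------------------------------------------
# safe arithmetic expressions

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
}
_FUNCS = {"max": max, "min": min}


def eval_expr(expr, env: dict[str, float]) -> float:
    """Evaluate a number, parameter name, or arithmetic expression."""
    if isinstance(expr, (int, float)):
        return float(expr)

    def _ev(node):
        if isinstance(node, ast.Expression):
            return _ev(node.body)
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return float(node.value)
        if isinstance(node, ast.Name):
            if node.id not in env:
                raise KeyError(f"unbound parameter {node.id!r}")
            return float(env[node.id])
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            return _BINOPS[type(node.op)](_ev(node.left), _ev(node.right))
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            return -_ev(node.operand)
        if isinstance(node, ast.Call) and isinstance(node.func, ast.Name):
            fn = _FUNCS.get(node.func.id)
            if fn is None:
                raise ValueError(f"function {node.func.id!r} not allowed")
            return fn(*[_ev(a) for a in node.args])
        raise ValueError(f"unsupported expression element {ast.dump(node)}")

    return _ev(ast.parse(str(expr), mode="eval"))


# ---------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class DemeSpec:
    name: str
    N: float | str  # diploid effective size or parameter expression
    sample_n: int  # haploid sample size

    def __post_init__(self) -> None:
        if self.sample_n < 0 or self.sample_n % 2:
            raise ValueError("sample_n must be a non-negative even number")


@dataclass(frozen=True)
class MergeEvent:
    t: float | str
    source: str
    dest: str

    def __post_init__(self) -> None:
        if self.source == self.dest:
            raise ValueError("merge source and dest must differ")


@dataclass(frozen=True)
class AdmixtureEvent:
    t: float | str
    hybrid: str
    parent_a: str
    parent_b: str
    alpha: float | str  # proportion of hybrid lineages tracing to parent_a

    def __post_init__(self) -> None:
        if self.hybrid in (self.parent_a, self.parent_b):
            raise ValueError("hybrid deme cannot be its own parent")


@dataclass(frozen=True)
class SizeChangeEvent:
    t: float | str
    deme: str
    new_N: float | str
    role: str = ""  # e.g. "bottleneck" / "ancestral"


@dataclass(frozen=True)
class MigrationEpoch:
    """Backward migration rates over [t_start, t_end) (times in generations)."""

    t_start: float
    t_end: float
    rates: dict  # (from_deme, to_deme) -> rate

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    low: float
    high: float
    scale: str = "linear"  # "linear" | "log"
    kind: str = "other"  # "size" | "time" | "rate" | "proportion"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")


_EVENT_TYPES = {"MergeEvent": MergeEvent, "AdmixtureEvent": AdmixtureEvent, "SizeChangeEvent": SizeChangeEvent}


@dataclass
class DemographicModel:
    name: str
    demes: list[DemeSpec]
    events: list  # Merge/Admixture/SizeChange events (expressions allowed)
    migration: dict  # (from, to) -> rate or parameter name
    params: list[ParameterSpec]  # free parameters
    constraints: list[tuple[str, str]] = field(default_factory=list)  # (younger, older)
    fixed: dict[str, float] = field(default_factory=dict)
    submodel: str = ""

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.params)

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    @property
    def deme_names(self) -> list[str]:
        return [d.name for d in self.demes]

    @property
    def sample_sizes(self) -> dict[str, int]:
        return {d.name: d.sample_n for d in self.demes}

    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    def bind(self, params) -> dict[str, float]:
        """Merge free-parameter values (dict or vector in params order) with
        fixed values into a full name -> value environment."""
        if params is None:
            params = {}
        if not isinstance(params, dict):
            vec = np.asarray(params, dtype=float)
            if vec.size != len(self.params):
                raise ValueError(f"expected {len(self.params)} values, got {vec.size}")
            params = dict(zip(self.param_names(), vec))
        env = dict(self.fixed)
        env.update(params)
        missing = [p.name for p in self.params if p.name not in env]
        if missing:
            raise ValueError(f"unbound parameters: {missing}")
        return env

    def concrete_events(self, env: dict[str, float]) -> list:
        """Events with all expressions resolved, sorted by time."""
        out = []
        for ev in self.events:
            if isinstance(ev, MergeEvent):
                out.append(MergeEvent(eval_expr(ev.t, env), ev.source, ev.dest))
            elif isinstance(ev, AdmixtureEvent):
                out.append(
                    AdmixtureEvent(
                        eval_expr(ev.t, env), ev.hybrid, ev.parent_a, ev.parent_b,
                        eval_expr(ev.alpha, env),
                    )
                )
            else:
                out.append(
                    SizeChangeEvent(eval_expr(ev.t, env), ev.deme, eval_expr(ev.new_N, env), ev.role)
                )
        return sorted(out, key=lambda e: e.t)

    def migration_matrix(self, env: dict[str, float]) -> np.ndarray:
        """Base backward migration matrix in deme order (extant epoch)."""
        names = self.deme_names
        M = np.zeros((len(names), len(names)))
        for (a, b), rate in self.migration.items():
            M[names.index(a), names.index(b)] = eval_expr(rate, env)
        return M

    def migration_epochs(self, env: dict[str, float]) -> list[MigrationEpoch]:
        """Epoch view of migration: rates zero once either deme is extinct."""
        events = self.concrete_events(env)
        extinct_at: dict[str, float] = {}
        for ev in events:
            if isinstance(ev, MergeEvent):
                extinct_at[ev.source] = ev.t
            elif isinstance(ev, AdmixtureEvent):
                extinct_at[ev.hybrid] = ev.t
        cuts = sorted({0.0, *extinct_at.values(), max((e.t for e in events), default=0.0) + 1.0})
        epochs = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            rates = {
                (a, b): eval_expr(r, env)
                for (a, b), r in self.migration.items()
                if extinct_at.get(a, np.inf) > lo and extinct_at.get(b, np.inf) > lo
            }
            epochs.append(MigrationEpoch(lo, hi, rates))
        return epochs

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        def enc(ev):
            d = asdict(ev)
            d["type"] = type(ev).__name__
            return d

        return json.dumps(
            {
                "name": self.name,
                "submodel": self.submodel,
                "demes": [asdict(d) for d in self.demes],
                "events": [enc(e) for e in self.events],
                "migration": [[a, b, r] for (a, b), r in self.migration.items()],
                "params": [asdict(p) for p in self.params],
                "constraints": [list(c) for c in self.constraints],
                "fixed": self.fixed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DemographicModel":
        d = json.loads(text)
        events = []
        for e in d["events"]:
            typ = _EVENT_TYPES[e.pop("type")]
            events.append(typ(**e))
        return cls(
            name=d["name"],
            submodel=d.get("submodel", ""),
            demes=[DemeSpec(**x) for x in d["demes"]],
            events=events,
            migration={(a, b): r for a, b, r in d["migration"]},
            params=[ParameterSpec(**x) for x in d["params"]],
            constraints=[tuple(c) for c in d["constraints"]],
            fixed=d.get("fixed", {}),
        )


# ---------------------------------------------------------------------------
# event-order validation


def validate_event_order(model: DemographicModel, params) -> list[str]:
    """Check a concrete parameter vector against the model's time topology.

    Returns a list of violation strings (empty when valid): negative event
    times, child events older than their parents, a non-maximal root
    divergence time, or bottleneck windows crossed by another event on the
    same deme.
    """
    env = model.bind(params)
    violations: list[str] = []
    events = model.concrete_events(env)

    for ev in events:
        if ev.t < 0:
            violations.append(f"event at negative time {ev.t}: {ev}")

    # strictly younger: a time tie would make the backward event order
    # ambiguous (e.g. a child deme merging into an already-extinct parent)
    for younger, older in model.constraints:
        if env[younger] >= env[older]:
            violations.append(
                f"order constraint violated: {younger}={env[younger]:g} "
                f">= {older}={env[older]:g}"
            )

    if "TDIV_ANC" in env:
        t_anc = env["TDIV_ANC"]
        time_params = {p.name for p in model.params if p.kind == "time"} | {
            k for k in model.fixed if k.startswith(("TDIV", "THYB"))
        }
        for name in time_params:
            if name != "TDIV_ANC" and env[name] >= t_anc:
                violations.append(
                    f"{name}={env[name]:g} is not strictly below TDIV_ANC={t_anc:g}"
                )

    # bottleneck windows must not be crossed by another event on the hybrid deme
    for adm in (e for e in events if isinstance(e, AdmixtureEvent)):
        lo = max(adm.t - BOTTLENECK_GENERATIONS, 0.0)
        for ev in events:
            if ev is adm or isinstance(ev, SizeChangeEvent) and ev.role == "bottleneck":
                continue
            deme_of = (
                ev.deme
                if isinstance(ev, SizeChangeEvent)
                else ev.source
                if isinstance(ev, MergeEvent)
                else ev.hybrid
            )
            if deme_of == adm.hybrid and lo < ev.t < adm.t:
                violations.append(
                    f"event {ev} falls inside the bottleneck window ({lo:g}, {adm.t:g}) of {adm.hybrid}"
                )
    return violations


# ---------------------------------------------------------------------------
# catalogue builders

MODEL_NAMES = [
    "3-dicho",
    "3-dicho+mig",
    "3-hybGAL",
    "4-dicho",
    "4-dicho+mig",
    "4-hybSPW",
    "4-hybGALearly",
    "4-hybGALearly+mig",
    "4-hybGALlate",
    "4-hybGAL+hybSPW",
    "4-hybGALSPW",
]

_SUBMODEL_NAMES = {"4-dicho", "4-dicho+mig"}


def _p_size(name):
    return ParameterSpec(name, *SIZE_RANGE, scale="log", kind="size")


def _p_time(name, rng=TIME_RANGE):
    return ParameterSpec(name, *rng, scale="linear", kind="time")


def _p_mig(name):
    return ParameterSpec(name, *MIG_RANGE, scale="log", kind="rate")


def _p_alpha(name):
    return ParameterSpec(name, *ALPHA_RANGE, scale="linear", kind="proportion")


def _mig_pair(a: str, b: str):
    """Two directional migration parameters plus their matrix entries."""
    pa, pb = f"MIG_{a}_{b}", f"MIG_{b}_{a}"
    return [_p_mig(pa), _p_mig(pb)], {(a, b): pa, (b, a): pb}


def _bottleneck(hybrid: str, t_expr: str, present_N: str) -> list[SizeChangeEvent]:
    """Size-change pair: 0.5% of present size for the 50 generations after founding."""
    return [
        SizeChangeEvent(
            t=f"max({t_expr} - {BOTTLENECK_GENERATIONS:g}, 0)",
            deme=hybrid,
            new_N=f"{BOTTLENECK_FRACTION} * {present_N}",
            role="bottleneck",
        ),
        SizeChangeEvent(t=t_expr, deme=hybrid, new_N=present_N, role="bottleneck"),
    ]


def build_model(
    name: str,
    submodel: str = "a",
    overrides: dict[str, float] | None = None,
    sample_sizes: dict[str, int] | None = None,
) -> DemographicModel:
    """Build one of the named speciation models.

    ``submodel`` ('a' or 'b') selects the divergence order for the 4-deme
    dichotomous models: 'a' has the Pnig/Pgal split older than the
    PspE/PspW split, 'b' the reverse. ``overrides`` fixes named parameters
    to given values (they leave the free-parameter list); values must lie
    inside the parameter's search range. ``sample_sizes`` replaces the
    default haploid sample sizes (useful for reduced-scale experiments).
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; valid names: {MODEL_NAMES}")
    if name in _SUBMODEL_NAMES and submodel not in ("a", "b"):
        raise ValueError(f"model {name} requires submodel 'a' or 'b'")

    three = name.startswith("3-")
    ns = dict(SAMPLES_3DEME if three else SAMPLES_4DEME)
    if sample_sizes:
        ns.update(sample_sizes)

    if three:
        demes = [
            DemeSpec("Pgal", "N_Pgal", ns["Pgal"]),
            DemeSpec("Pnig", "N_Pnig", ns["Pnig"]),
            DemeSpec("Pspi", "N_Pspi", ns["Pspi"]),
        ]
        params = [_p_size("N_Pgal"), _p_size("N_Pnig"), _p_size("N_Pspi")]
        mig_params, migration = _mig_pair("Pnig", "Pspi")  # background gene flow
        params += mig_params
        events: list = [
            MergeEvent(t="TDIV_ANC", source="Pnig", dest="Pspi"),
            SizeChangeEvent(t="TDIV_ANC", deme="Pspi", new_N="N_ANC", role="ancestral"),
        ]
        params += [_p_size("N_ANC"), _p_time("TDIV_ANC", TDIV_ANC_RANGE)]
        constraints: list[tuple[str, str]] = []

        if name in ("3-dicho", "3-dicho+mig"):
            events += [
                MergeEvent(t="TDIV_GAL", source="Pgal", dest="Pnig"),
                SizeChangeEvent(t="TDIV_GAL", deme="Pnig", new_N="N_ANC_GN", role="ancestral"),
            ]
            params += [_p_size("N_ANC_GN"), _p_time("TDIV_GAL")]
            constraints.append(("TDIV_GAL", "TDIV_ANC"))
            if name == "3-dicho+mig":
                mp, mm = _mig_pair("Pgal", "Pspi")
                params += mp
                migration.update(mm)
        else:  # 3-hybGAL
            events += _bottleneck("Pgal", "THYB_GAL", "N_Pgal")
            events.append(
                AdmixtureEvent(
                    t="THYB_GAL", hybrid="Pgal", parent_a="Pnig", parent_b="Pspi",
                    alpha="ALPHA_gal",
                )
            )
            params += [_p_time("THYB_GAL"), _p_alpha("ALPHA_gal")]
            constraints.append(("THYB_GAL", "TDIV_ANC"))
    else:
        demes = [
            DemeSpec("Pgal", "N_Pgal", ns["Pgal"]),
            DemeSpec("Pnig", "N_Pnig", ns["Pnig"]),
            DemeSpec("PspE", "N_PspE", ns["PspE"]),
            DemeSpec("PspW", "N_PspW", ns["PspW"]),
        ]
        params = [_p_size(f"N_{d}") for d in ("Pgal", "Pnig", "PspE", "PspW")]
        # background gene flow: Pnig<->PspE (their ranges overlap) and
        # PspW<->PspE (admixed contact zone) in all 4-deme models
        mp1, migration = _mig_pair("Pnig", "PspE")
        mp2, mm2 = _mig_pair("PspW", "PspE")
        migration.update(mm2)
        params += mp1 + mp2
        events = [
            MergeEvent(t="TDIV_ANC", source="Pnig", dest="PspE"),
            SizeChangeEvent(t="TDIV_ANC", deme="PspE", new_N="N_ANC", role="ancestral"),
        ]
        params += [_p_size("N_ANC"), _p_time("TDIV_ANC", TDIV_ANC_RANGE)]
        constraints = []

        def split_spw():
            events.append(MergeEvent(t="TDIV_SPW", source="PspW", dest="PspE"))
            events.append(
                SizeChangeEvent(t="TDIV_SPW", deme="PspE", new_N="N_ANC_SP", role="ancestral")
            )
            params.append(_p_size("N_ANC_SP"))
            params.append(_p_time("TDIV_SPW"))
            constraints.append(("TDIV_SPW", "TDIV_ANC"))

        def split_gal():
            events.append(MergeEvent(t="TDIV_GAL", source="Pgal", dest="Pnig"))
            events.append(
                SizeChangeEvent(t="TDIV_GAL", deme="Pnig", new_N="N_ANC_GN", role="ancestral")
            )
            params.append(_p_size("N_ANC_GN"))
            params.append(_p_time("TDIV_GAL"))
            constraints.append(("TDIV_GAL", "TDIV_ANC"))

        if name in ("4-dicho", "4-dicho+mig"):
            split_gal()
            split_spw()
            # divergence-order submodels
            if submodel == "a":
                constraints.append(("TDIV_SPW", "TDIV_GAL"))
            else:
                constraints.append(("TDIV_GAL", "TDIV_SPW"))
            if name == "4-dicho+mig":
                mp, mm = _mig_pair("Pgal", "PspW")
                params += mp
                migration.update(mm)
        elif name == "4-hybSPW":
            split_gal()
            events += _bottleneck("PspW", "THYB_SPW", "N_PspW")
            events.append(
                AdmixtureEvent(
                    t="THYB_SPW", hybrid="PspW", parent_a="Pgal", parent_b="PspE",
                    alpha="ALPHA_spw",
                )
            )
            params += [_p_time("THYB_SPW"), _p_alpha("ALPHA_spw")]
            constraints.append(("THYB_SPW", "TDIV_GAL"))
        elif name in ("4-hybGALearly", "4-hybGALearly+mig"):
            split_spw()
            events += _bottleneck("Pgal", "THYB_GAL", "N_Pgal")
            events.append(
                AdmixtureEvent(
                    t="THYB_GAL", hybrid="Pgal", parent_a="Pnig", parent_b="PspE",
                    alpha="ALPHA_gal",
                )
            )
            params += [_p_time("THYB_GAL"), _p_alpha("ALPHA_gal")]
            # the spicatum parent is the ancestor of both lineages
            constraints += [("TDIV_SPW", "THYB_GAL"), ("THYB_GAL", "TDIV_ANC")]
            if name == "4-hybGALearly+mig":
                mp, mm = _mig_pair("Pgal", "PspW")
                params += mp
                migration.update(mm)
        elif name == "4-hybGALlate":
            split_spw()
            events += _bottleneck("Pgal", "THYB_GAL", "N_Pgal")
            events.append(
                AdmixtureEvent(
                    t="THYB_GAL", hybrid="Pgal", parent_a="Pnig", parent_b="PspW",
                    alpha="ALPHA_gal",
                )
            )
            params += [_p_time("THYB_GAL"), _p_alpha("ALPHA_gal")]
            # western spicatum is a parent, so it must already exist
            constraints.append(("THYB_GAL", "TDIV_SPW"))
        elif name == "4-hybGAL+hybSPW":
            events += _bottleneck("PspW", "THYB_SPW", "N_PspW")
            events.append(
                AdmixtureEvent(
                    t="THYB_SPW", hybrid="PspW", parent_a="Pgal", parent_b="PspE",
                    alpha="ALPHA_spw",
                )
            )
            events += _bottleneck("Pgal", "THYB_GAL", "N_Pgal")
            events.append(
                AdmixtureEvent(
                    t="THYB_GAL", hybrid="Pgal", parent_a="Pnig", parent_b="PspE",
                    alpha="ALPHA_gal",
                )
            )
            params += [
                _p_time("THYB_SPW"), _p_alpha("ALPHA_spw"),
                _p_time("THYB_GAL"), _p_alpha("ALPHA_gal"),
            ]
            constraints += [("THYB_SPW", "THYB_GAL"), ("THYB_GAL", "TDIV_ANC")]
        else:  # 4-hybGALSPW: shared Pgal/PspW ancestor of hybrid origin
            events.append(MergeEvent(t="TDIV_GW", source="PspW", dest="Pgal"))
            events.append(
                SizeChangeEvent(t="TDIV_GW", deme="Pgal", new_N="N_ANC_GW", role="ancestral")
            )
            events += _bottleneck("Pgal", "THYB_GW", "N_ANC_GW")
            events.append(
                AdmixtureEvent(
                    t="THYB_GW", hybrid="Pgal", parent_a="Pnig", parent_b="PspE",
                    alpha="ALPHA_gw",
                )
            )
            params += [
                _p_size("N_ANC_GW"), _p_time("TDIV_GW"),
                _p_time("THYB_GW"), _p_alpha("ALPHA_gw"),
            ]
            constraints += [("TDIV_GW", "THYB_GW"), ("THYB_GW", "TDIV_ANC")]

    model = DemographicModel(
        name=name,
        submodel=submodel if name in _SUBMODEL_NAMES else "",
        demes=demes,
        events=events,
        migration=migration,
        params=params,
        constraints=constraints,
    )

    if overrides:
        by_name = {p.name: p for p in model.params}
        for pname, val in overrides.items():
            if pname not in by_name:
                raise ValueError(f"override for unknown parameter {pname!r}")
            p = by_name[pname]
            if not p.low <= val <= p.high:
                raise ValueError(
                    f"override {pname}={val} outside range [{p.low}, {p.high}]"
                )
            model.fixed[pname] = float(val)
        model.params = [p for p in model.params if p.name not in overrides]
    return model


def model_catalogue() -> list[DemographicModel]:
    """All named specifications: 3 three-deme and 10 four-deme rows
    (two submodels each for the dichotomous 4-deme models)."""
    out = []
    for name in MODEL_NAMES:
        if name in _SUBMODEL_NAMES:
            out.append(build_model(name, "a"))
            out.append(build_model(name, "b"))
        else:
            out.append(build_model(name))
    return out
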