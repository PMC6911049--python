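"""JSON serialization of parameter sets and packaged fixtures.

Fixtures ``ci2_wt.json`` and ``ci2_eng.json`` carry the published
two-state equilibrium and chevron parameters of wild-type CI2 and the
engineered fold-switching variant (signal baselines are conventional
defaults, since only the thermodynamic/kinetic parameters are reported).
The linkage fixtures carry tuning constants for the five-species scheme
chosen to reproduce the qualitative behavior of the system; they are not
measured values (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources

from .composition import SequenceRecord, read_fasta
from .linkage import AssociationStepParams, LinkageParams
from .twostate import ChevronParams, LinearBaseline, ThermalStepParams, TwoStateChemParams

__all__ = [
    "load_fixture",
    "chem_params",
    "chevron_params",
    "linkage_params",
    "sequences",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

_PARAM_TYPES = {
    "TwoStateChemParams": TwoStateChemParams,
    "ChevronParams": ChevronParams,
    "ThermalStepParams": ThermalStepParams,
    "AssociationStepParams": AssociationStepParams,
    "LinkageParams": LinkageParams,
    "LinearBaseline": LinearBaseline,
}


def params_to_dict(obj) -> dict:
    """Dataclass parameter set -> plain dict with a ``__type__`` tag."""
    d = {"__type__": type(obj).__name__}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        d[f.name] = params_to_dict(v) if dataclasses.is_dataclass(v) else v
    return d


def params_from_dict(d: dict):
    """Inverse of :func:`params_to_dict`."""
    cls = _PARAM_TYPES[d["__type__"]]
    kwargs = {}
    for k, v in d.items():
        if k == "__type__":
            continue
        kwargs[k] = params_from_dict(v) if isinstance(v, dict) and "__type__" in v else v
    return cls(**kwargs)


def save_params(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(obj), fh, indent=2)


def load_params(path):
    with open(path) as fh:
        return params_from_dict(json.load(fh))


def load_fixture(name: str) -> dict:
    """Raw packaged fixture JSON by file stem (e.g. ``"ci2_wt"``)."""
    text = resources.files("foldlink.data").joinpath(f"{name}.json").read_text()
    return json.loads(text)


def chem_params(variant: str) -> TwoStateChemParams:
    """LEM parameters of ``"ci2_wt"`` or ``"ci2_eng"``."""
    d = load_fixture(variant)["chem"]
    return TwoStateChemParams(
        dG0=d["dG0"],
        m_eq=d["m_eq"],
        native=LinearBaseline(**d["native"]),
        unfolded=LinearBaseline(**d["unfolded"]),
    )


def chevron_params(variant: str) -> ChevronParams:
    """Chevron parameters of ``"ci2_wt"`` or ``"ci2_eng"``."""
    return ChevronParams(**load_fixture(variant)["chevron"])


def linkage_params(variant: str) -> LinkageParams:
    """Five-species linkage fixture: ``"ci2_eng"`` or ``"ci2_1_58"``."""
    d = load_fixture(f"linkage_{variant}")
    return LinkageParams(
        step_NS=ThermalStepParams(**d["step_NS"]),
        step_NU=ThermalStepParams(**d["step_NU"]),
        assoc_H=AssociationStepParams(**d["assoc_H"]),
        assoc_H2=AssociationStepParams(**d["assoc_H2"]),
        bind_P=AssociationStepParams(**d["bind_P"]),
    )


def sequences() -> dict[str, SequenceRecord]:
    """Packaged one-letter sequences of the CI2 variants, keyed by id."""
    with resources.as_file(resources.files("foldlink.data").joinpath("sequences.fasta")) as p:
        return {rec.identifier: rec for rec in read_fasta(p)}
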