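"""Plain-text persistence: JSON headers plus CSV matrices.

A register is stored as ``<stem>.json`` (label, geometry, format version)
next to ``<stem>.csv`` holding the ``n x m`` integer weight matrix; a system
is a directory with a manifest, a quantizer file and one register per class.
Round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from wamr.core import RecognitionParams, WeightedAMR
from wamr.quantization import Quantizer
from wamr.system import MemorySystem

FORMAT_VERSION = 1


def save_amr(amr: WeightedAMR, stem: Union[str, Path]) -> None:
    stem = Path(stem)
    header = {
        "format_version": FORMAT_VERSION,
        "kind": "amr",
        "label": amr.label,
        "n_cols": amr.n_cols,
        "n_rows": amr.n_rows,
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=2))
    np.savetxt(stem.with_suffix(".csv"), amr.weights, fmt="%d", delimiter=",")


def load_amr(stem: Union[str, Path]) -> WeightedAMR:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    if header.get("kind") != "amr":
        raise ValueError(f"{stem} does not hold a register")
    weights = np.loadtxt(
        stem.with_suffix(".csv"), dtype=np.int64, delimiter=",", ndmin=2
    )
    return WeightedAMR(
        n_cols=header["n_cols"],
        n_rows=header["n_rows"],
        label=header["label"],
        weights=weights,
    )


def save_quantizer(q: Quantizer, path: Union[str, Path]) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "quantizer",
        "n_dims": q.n_dims,
        "n_levels": q.n_levels,
        "lo": q.lo.tolist(),
        "hi": q.hi.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_quantizer(path: Union[str, Path]) -> Quantizer:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "quantizer":
        raise ValueError(f"{path} does not hold a quantizer")
    return Quantizer(
        n_dims=payload["n_dims"],
        n_levels=payload["n_levels"],
        lo=np.array(payload["lo"]),
        hi=np.array(payload["hi"]),
    )


def _label_stem(label: str) -> str:
    # phone symbols like "r(" and "n~" are not filesystem-friendly
    return "reg_" + "".join(f"{ord(ch):02x}" for ch in label)


def save_system(sys: MemorySystem, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "kind": "memory_system",
        "labels": sorted(sys.registers),
        "params": {
            "iota": sys.params.iota,
            "kappa": sys.params.kappa,
            "xi": sys.params.xi,
            "sigma": sys.params.sigma,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    save_quantizer(sys.quantizer, directory / "quantizer.json")
    for label, amr in sys.registers.items():
        save_amr(amr, directory / _label_stem(label))


def load_system(directory: Union[str, Path]) -> MemorySystem:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("kind") != "memory_system":
        raise ValueError(f"{directory} does not hold a memory system")
    params = RecognitionParams(**manifest["params"])
    quantizer = load_quantizer(directory / "quantizer.json")
    registers = {
        label: load_amr(directory / _label_stem(label))
        for label in manifest["labels"]
    }
    return MemorySystem(registers=registers, quantizer=quantizer, params=params)
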