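"""The published primer catalogue, packaged as TSV.

Pairs are assembled from rows sharing the name prefix before the -F/-R
suffix; the AG primers carry degenerate bases (K, W, S, R).
"""
from __future__ import annotations

import functools
from importlib import resources
from typing import Dict, List

from .models import Primer, PrimerPair


def _data_path():
    return resources.files("figmark").joinpath("data/primers.tsv")


@functools.lru_cache(maxsize=1)
def default_primer_pairs() -> List[PrimerPair]:
    from .io import read_primer_table

    with resources.as_file(_data_path()) as path:
        return read_primer_table(path)


@functools.lru_cache(maxsize=1)
def _primer_index() -> Dict[str, Primer]:
    out: Dict[str, Primer] = {}
    for pair in default_primer_pairs():
        out[pair.forward.name] = pair.forward
        out[pair.reverse.name] = pair.reverse
    return out


def primer_by_name(name: str) -> Primer:
    return _primer_index()[name]


def pair_by_name(name: str) -> PrimerPair:
    for pair in default_primer_pairs():
        if pair.name == name:
            return pair
    raise KeyError(name)
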