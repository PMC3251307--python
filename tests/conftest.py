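"""Shared fixtures: synthetic projects and a random-track fuzzer."""

from __future__ import annotations

import random

import pytest

from genomap import fixtures as fx
from genomap.formats import (BlastHit, ColouredFeature, Feature,
                             GradientSpec, Track, ValuedFeature)

COLOUR_NAMES = ["clBlack", "clRed", "clBlue", "clGreen", "clNavy", "clOlive"]
STRANDS = ["+", "-", "."]


def random_feature(rng: random.Random, chrom_ids=("1", "2", "3"),
                   max_nt: int = 100_000) -> Feature:
    first = rng.randint(1, max_nt)
    last = first + rng.randint(0, 5_000)
    return Feature(
        chrom_id=rng.choice(chrom_ids),
        first_nt=first,
        last_nt=last,
        strand=rng.choice(STRANDS),
        feature_id=f"f{rng.randint(1, 99999)}",
        extras=tuple(f"note {rng.randint(0, 999)}"
                     for _ in range(rng.randint(0, 2))),
    )


def random_track(rng: random.Random, kind: str, name: str = "fuzz",
                 n_max: int = 12) -> Track:
    """A random valid track of the given kind.

    Blast hits are generated at or below the cut-off so that writing
    and re-parsing is lossless (the parser drops hits above the
    cut-off by contract; retention is tested separately).
    """
    n = rng.randint(0, n_max)
    base = [random_feature(rng) for _ in range(n)]
    if kind == "posn":
        return Track(name=name, kind="posn",
                     colour=rng.choice(COLOUR_NAMES), records=base)
    if kind == "blast":
        cutoff = 10.0 ** rng.uniform(-12, -2)
        records = []
        for f in base:
            pairs = sorted(
                ((f"q{rng.randint(1, 999)}",
                  cutoff * 10 ** rng.uniform(-8, 0))
                 for _ in range(rng.randint(1, 3))),
                key=lambda p: p[1],
            )
            records.append(BlastHit(
                chrom_id=f.chrom_id, first_nt=f.first_nt, last_nt=f.last_nt,
                strand=f.strand, feature_id=rng.choice([f.feature_id, "seq"]),
                pairs=tuple(pairs)))
        return Track(name=name, kind="blast",
                     colour=rng.choice(COLOUR_NAMES), cutoff=cutoff,
                     records=records)
    if kind == "expr":
        records = [ColouredFeature(
            chrom_id=f.chrom_id, first_nt=f.first_nt, last_nt=f.last_nt,
            strand=f.strand, feature_id=f.feature_id, extras=f.extras,
            colour=rng.choice(COLOUR_NAMES)) for f in base]
        return Track(name=name, kind="expr", records=records)
    if kind in ("freq", "graph"):
        records = [ValuedFeature(
            chrom_id=f.chrom_id, first_nt=f.first_nt, last_nt=f.last_nt,
            strand=f.strand, feature_id=f.feature_id, extras=f.extras,
            value=round(rng.uniform(-20, 20), 4)) for f in base]
        if kind == "freq":
            k = rng.randint(1, 6)
            bounds = sorted(rng.sample(range(-50, 50), k - 1))
            gradient = GradientSpec(
                colours=tuple(f"clC{i}" for i in range(k)),
                boundaries=tuple(float(b) for b in bounds))
            return Track(name=name, kind="freq", gradient=gradient,
                         records=records)
        return Track(name=name, kind="graph",
                     colour=rng.choice([None, "clNavy"]), records=records)
    raise ValueError(kind)


@pytest.fixture
def track_fuzzer():
    return random_track


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    root = tmp_path_factory.mktemp("demo")
    return fx.make_worked_example(root / "project")


@pytest.fixture(scope="session")
def synthetic_project(tmp_path_factory):
    root = tmp_path_factory.mktemp("synth")
    spec = fx.SyntheticSpec(seed=11)
    truth = fx.make_project(spec, root / "project")
    return spec, truth
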