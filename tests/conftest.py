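"""Shared fixtures: synthetic input directories and small hand-built objects."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mgogp import (ExpressionData, FixtureSpec, GoKnowledge, generate,
                   read_expression, read_gmt, read_go, read_seed_genes)
from mgogp.fixtures import null_spec


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default planted-signal fixture (500 genes, 50+50 samples)."""
    out = tmp_path_factory.mktemp("fixture_default")
    manifest = generate(FixtureSpec(rng_seed=101), out)
    return out, manifest


@pytest.fixture(scope="session")
def null_fixture_dir(tmp_path_factory):
    """No-signal fixture (1000 genes) for null-calibration checks."""
    out = tmp_path_factory.mktemp("fixture_null")
    manifest = generate(null_spec(rng_seed=102), out)
    return out, manifest


@pytest.fixture(scope="session")
def expr(fixture_dir) -> ExpressionData:
    path, _ = fixture_dir
    return read_expression(path / "expression.tsv", path / "conditions.tsv")


@pytest.fixture(scope="session")
def modules(fixture_dir, expr):
    path, _ = fixture_dir
    return read_gmt(path / "modules.gmt").restrict_to(expr.gene_ids)


@pytest.fixture(scope="session")
def go(fixture_dir) -> GoKnowledge:
    path, _ = fixture_dir
    return read_go(path / "annotations.tsv", path / "go.obo")


@pytest.fixture(scope="session")
def seeds(fixture_dir):
    path, _ = fixture_dir
    return read_seed_genes(path / "seeds.txt")


def make_expression(values: np.ndarray, n_normal: int, n_tumor: int,
                    genes: list[str] | None = None) -> ExpressionData:
    """Build a validated ExpressionData from a raw array."""
    n_genes = values.shape[0]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"N{i}" for i in range(n_normal)] + [f"T{i}" for i in range(n_tumor)]
    condition = pd.Series(["normal"] * n_normal + ["tumor"] * n_tumor, index=samples)
    return ExpressionData(
        values=pd.DataFrame(values, index=genes, columns=samples),
        condition=condition,
    )


def diamond_go() -> GoKnowledge:
    """t4 is_a {t2, t3}; t2, t3 is_a t1 — two paths from t4 to the root."""
    dag = nx.DiGraph()
    dag.add_edges_from([("t2", "t1"), ("t3", "t1"), ("t4", "t2"), ("t4", "t3")])
    annotations = {
        "gA": frozenset({"t4"}),
        "gB": frozenset({"t2"}),
        "gC": frozenset({"t3"}),
        "gD": frozenset({"t1"}),
    }
    return GoKnowledge(annotations=annotations, dag=dag)
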