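from __future__ import annotations

import csv
from pathlib import Path

import pytest

from aopnet import read_aop_tables

HEADER = [
    "aop_id",
    "upstream_title",
    "upstream_type",
    "downstream_title",
    "downstream_type",
    "adjacency",
    "woe",
]


def write_rows(path: Path, rows: list[list[object]], header: list[str] | None = None) -> Path:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header or HEADER)
        writer.writerows(rows)
    return path


def collection_from_rows(tmp_path: Path, rows: list[list[object]], name: str = "table.csv"):
    return read_aop_tables(write_rows(tmp_path / name, rows))


@pytest.fixture
def linear_collection(tmp_path):
    """One pathway: M -> K -> A."""
    return collection_from_rows(
        tmp_path,
        [
            [1, "M", "MIE", "K", "KE", "adjacent", "high"],
            [1, "K", "KE", "A", "AO", "adjacent", "medium"],
        ],
    )


@pytest.fixture
def diamond_collection(tmp_path):
    """Two pathways M -> A -> Z and M -> B -> Z sharing endpoints."""
    return collection_from_rows(
        tmp_path,
        [
            [1, "M", "MIE", "A", "KE", "adjacent", "high"],
            [1, "A", "KE", "Z", "AO", "adjacent", "high"],
            [2, "M", "MIE", "B", "KE", "adjacent", "low"],
            [2, "B", "KE", "Z", "AO", "adjacent", ""],
        ],
    )


@pytest.fixture
def feedback_collection(tmp_path):
    """Entry M -> A with cycle A <-> B and exit B -> Z."""
    return collection_from_rows(
        tmp_path,
        [
            [1, "M", "MIE", "A", "KE", "adjacent", "high"],
            [1, "A", "KE", "B", "KE", "adjacent", ""],
            [1, "B", "KE", "A", "KE", "adjacent", ""],
            [1, "B", "KE", "Z", "AO", "adjacent", "medium"],
        ],
    )
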