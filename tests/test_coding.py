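"""Label enumeration, target encodings and decoders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgpr.coding import (
    decode_batch,
    decode_multiple,
    decode_per_dof,
    decode_single,
    encode_targets,
    enumerate_labels,
    export_label_table,
)


@pytest.mark.parametrize("n_dof,expected", [(1, 3), (2, 9), (3, 27)])
def test_enumeration_size(n_dof, expected):
    labels = enumerate_labels(n_dof)
    assert len(labels) == expected
    states = {lab.dof_state for lab in labels}
    assert len(states) == expected  # no duplicates
    assert all(labels[i].class_index == i for i in range(expected))


def test_three_dof_labels_are_26_movements_plus_rest(label_table):
    rest = [lab for lab in label_table if lab.is_rest]
    assert len(rest) == 1 and rest[0].name == "rest"
    assert sum(1 for lab in label_table if not lab.is_rest) == 26
    individual = [lab for lab in label_table if lab.n_active_dof == 1]
    assert len(individual) == 6


@given(n_dof=st.integers(min_value=1, max_value=4))
@settings(deadline=None)
def test_index_state_bijection(n_dof):
    labels = enumerate_labels(n_dof)
    assert len({lab.dof_state for lab in labels}) == 3 ** n_dof
    for lab in labels:
        digits = [s + 1 for s in lab.dof_state]
        idx = 0
        for d in digits:
            idx = idx * 3 + d
        assert idx == lab.class_index


def test_encoding_invariants(label_table):
    single = encode_targets(label_table, "single").targets
    assert single.shape == (27, 27)
    assert np.array_equal(single, np.eye(27))

    multiple = encode_targets(label_table, "multiple").targets
    assert multiple.shape == (27, 6)
    assert np.all(multiple.sum(axis=1) <= 3)
    # never both units of one DoF
    for d in range(3):
        assert not np.any((multiple[:, 2 * d] == 1) & (multiple[:, 2 * d + 1] == 1))

    per_dof = encode_targets(label_table, "per_dof").targets
    blocks = per_dof.reshape(27, 3, 4)
    assert np.all(blocks.sum(axis=2) == 1)  # each block one-hot


def test_multiple_encoding_example(label_table):
    # state (+1, 0, -1): open agonist unit and pronation-DoF antagonist unit
    lab = next(l for l in label_table if l.dof_state == (1, 0, -1))
    row = encode_targets([lab], "multiple").targets[0]
    assert row.tolist() == [1, 0, 0, 0, 0, 1]


def test_per_dof_rest_encoding(label_table):
    rest = label_table[13]
    assert rest.is_rest
    row = encode_targets([rest], "per_dof").targets[0].reshape(3, 4)
    assert np.array_equal(row[:, 3], np.ones(3))


@pytest.mark.parametrize("scheme", ["single", "multiple", "per_dof"])
def test_encode_decode_identity_on_clean_targets(label_table, scheme):
    enc = encode_targets(label_table, scheme)
    decoded = decode_batch(enc.targets, scheme, label_table)
    if scheme == "per_dof":
        # "other" units map co-active DoF to inactive, so only labels with
        # <= 1 active DoF round-trip exactly; others lose co-activation
        for lab, dec in zip(label_table, decoded):
            if lab.n_active_dof <= 1:
                assert dec == lab
    else:
        assert decoded == label_table


def test_decode_single_tie_breaks_to_lowest_index(label_table):
    assert decode_single(np.ones(27), label_table).class_index == 0
    one_hot = np.zeros(27)
    one_hot[5] = 1
    assert decode_single(one_hot, label_table).class_index == 5


def test_decode_multiple_rules(label_table):
    assert decode_multiple(np.full(6, 0.1), label_table).is_rest
    lab = decode_multiple([0.9, 0.1, 0.2, 0.8, 0.3, 0.1], label_table)
    assert lab.dof_state == (1, -1, 0)
    # both units of DoF 1 active: larger output wins
    lab = decode_multiple([0.9, 0.8, 0.0, 0.0, 0.0, 0.0], label_table)
    assert lab.dof_state == (1, 0, 0)


def test_decode_per_dof_rules(label_table):
    rest_blocks = np.tile([0.0, 0.0, 0.1, 0.9], (3, 1))
    assert decode_per_dof(rest_blocks, label_table).is_rest
    blocks = np.array([
        [0.9, 0.0, 0.1, 0.0],   # agonist
        [0.0, 0.1, 0.8, 0.1],   # other -> inactive
        [0.0, 0.1, 0.8, 0.1],   # other -> inactive
    ])
    assert decode_per_dof(blocks, label_table).dof_state == (1, 0, 0)
    all_other = np.tile([0.0, 0.0, 0.9, 0.1], (3, 1))
    assert decode_per_dof(all_other, label_table).dof_state == (0, 0, 0)


def test_label_table_export(tmp_path, label_table):
    path = tmp_path / "labels.tsv"
    export_label_table(label_table, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 28
    assert lines[1].split("\t") == ["0", "close + extend + supination",
                                    "-1", "-1", "-1"]
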