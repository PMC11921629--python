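"""Shared fixtures: the toy reaction set and the rule database built from it.

Rule generation is deterministic but not free, so the fixture set, the
retained reactions, and the full rule database are built once per session.
"""

import pytest

from xenomet.fixtures import make_fixture_set
from xenomet.gem_io import filter_reactions
from xenomet.rule_generation import generate_rules_for_reaction


@pytest.fixture(scope="session")
def fixture_set():
    return make_fixture_set(seed=0)


@pytest.fixture(scope="session")
def retained_and_audit(fixture_set):
    return filter_reactions(list(fixture_set.reactions), balance_mode="strict")


@pytest.fixture(scope="session")
def retained(retained_and_audit):
    return retained_and_audit[0]


@pytest.fixture(scope="session")
def audit_log(retained_and_audit):
    return retained_and_audit[1]


@pytest.fixture(scope="session")
def rule_db(retained):
    rules = []
    for rec in retained:
        rules.extend(generate_rules_for_reaction(rec))
    return rules


@pytest.fixture(scope="session")
def queries_by_id(fixture_set):
    return {q.identifier: q for q in fixture_set.queries}
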