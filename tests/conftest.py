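import pytest

from nucassoc.scoring import ScoredNucleus, SignalObservation


def make_nucleus(
    nucleus_id,
    probes,
    ploidy="2C",
    tissue="leaf",
):
    """Build a ScoredNucleus from a compact probe spec.

    ``probes``: list of dicts with probe_id and optional homolog_index,
    signal_count, positions, flags.
    """
    observations = tuple(
        SignalObservation(
            probe_id=p["probe_id"],
            signal_count=p.get("signal_count", 1),
            homolog_index=p.get("homolog_index"),
            positions=p.get("positions"),
            flags=frozenset(p.get("flags", ())),
        )
        for p in probes
    )
    return ScoredNucleus(nucleus_id, ploidy, tissue, observations)


@pytest.fixture
def flagged_association_population():
    """200 2C nuclei, 27 of them with an associated probe pair (13.5%)."""
    nuclei = []
    for i in range(200):
        flags_a = ("associated_with:B",) if i < 27 else ()
        nuclei.append(
            make_nucleus(
                f"n{i:04d}",
                [
                    {"probe_id": "A", "flags": flags_a},
                    {"probe_id": "B"},
                ],
            )
        )
    return nuclei
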