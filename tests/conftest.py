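import numpy as np
import pytest

from speechtrf import Lexicon
from speechtrf.lexicon import EventTable


@pytest.fixture
def catcapdog() -> Lexicon:
    """The classic cohort toy: two prefix-sharing words plus a distractor."""
    return Lexicon(
        [
            ("cat", ("K", "AE", "T"), 2.0),
            ("cap", ("K", "AE", "P"), 1.0),
            ("dog", ("D", "AO", "G"), 1.0),
        ]
    )


def events_from_words(lexicon: Lexicon, words: list[str], dt: float = 0.1) -> EventTable:
    """Lay the words' phonemes out at a fixed inter-phoneme interval."""
    onsets, word_col, ph_col, init = [], [], [], []
    t = 0.0
    for w in words:
        for j, ph in enumerate(lexicon.transcription(w)):
            onsets.append(t)
            word_col.append(w)
            ph_col.append(ph)
            init.append(j == 0)
            t += dt
    return EventTable(np.array(onsets), word_col, ph_col, np.array(init), duration=t)


@pytest.fixture
def cat_dog_events(catcapdog) -> EventTable:
    return events_from_words(catcapdog, ["cat", "dog", "cap"])
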