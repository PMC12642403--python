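"""Build and summarize the context-model predictors.

Reads the simulated event table and lexicon, trains the phoneme and word
n-gram models on the simulated corpus, and computes surprisal / phoneme
entropy / cohort entropy at the sublexical, lexical and sentence context
levels.  Writes a per-event feature table and prints summary statistics.
"""

from pathlib import Path

import pandas as pd

from speechtrf import io as stio
from speechtrf.cohort import cohort_features
from speechtrf.features import sublexical_features
from speechtrf.ngram import train_ngram

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    events = stio.read_events(RESULTS / "events.tsv")
    lexicon = stio.read_lexicon(RESULTS / "lexicon.tsv")
    words = events.word_sequence()
    phonemes = events.phoneme_sequence()

    # phoneme 5-gram for the sublexical level (padded at utterance start)
    phone_lm = train_ngram(
        phonemes, order=5, discount=0.1, pad_symbol="<s>",
        extra_vocabulary=lexicon.inventory,
    )
    stio.write_arpa(RESULTS / "phoneme_5gram.arpa", phone_lm)
    sub = sublexical_features(events, phone_lm)

    # word-level prior for the sentence context model; a bigram is used at
    # this corpus size (a 5-gram would memorize the 200-word toy sequence)
    word_lm = train_ngram(words, order=2, discount=0.3, unk_symbol="<unk>")
    lex = cohort_features(events, lexicon, prior_mode="frequency")
    sent = cohort_features(
        events, lexicon, prior_mode="sentence-lm", word_lm=word_lm
    )

    table = pd.DataFrame(
        {
            "onset_s": events.onset_s,
            "phoneme": events.phoneme,
            "word_initial": events.word_initial,
            "sublexical_surprisal": sub.surprisal,
            "sublexical_phoneme_entropy": sub.phoneme_entropy,
            "lexical_surprisal": lex.surprisal,
            "lexical_phoneme_entropy": lex.phoneme_entropy,
            "lexical_cohort_entropy": lex.cohort_entropy,
            "sentence_surprisal": sent.surprisal,
            "sentence_phoneme_entropy": sent.phoneme_entropy,
            "sentence_cohort_entropy": sent.cohort_entropy,
        }
    )
    table.to_csv(RESULTS / "context_features.tsv", sep="\t", index=False)
    print(f"{len(table)} phoneme events; feature means (nats):")
    print(table.iloc[:, 3:].mean().round(3).to_string())
    print(
        "word-initial vs word-medial lexical surprisal: "
        f"{table[table.word_initial].lexical_surprisal.mean():.3f} vs "
        f"{table[~table.word_initial].lexical_surprisal.mean():.3f}"
    )


if __name__ == "__main__":
    main()
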