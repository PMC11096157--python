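#!/usr/bin/env python
"""Build few-shot NER prompt bundles for external language-model scoring.

For each shot count in {1, 5, 10, 20} a JSON-lines bundle is written: every
line holds one prompt (task description + worked examples + query) and the
gold annotated text for the query, over a 200-sentence test subsample.  No
model is called here; the bundles are the hand-off artifact.
"""

import argparse
import json
from pathlib import Path

from fedbionlp.corpus_io import dedup_split
from fedbionlp.prompting import (
    DEFAULT_NER_DESCRIPTION,
    PromptSpec,
    build_fewshot_prompt,
    render_annotated,
    sample_eval_subset,
)
from fedbionlp.synthetic import GenConfig, generate_ner, make_sources


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-eval", type=int, default=200)
    parser.add_argument("--out", type=Path, default=Path("results/prompts"))
    args = parser.parse_args()

    source = make_sources(1, 1.0, args.seed)[0]
    corpus = generate_ner(
        source, GenConfig(n_sentences=2500, tag_noise_rate=0.05, seed=args.seed)
    )
    train, _, test = dedup_split(corpus, seed=args.seed)
    subset = sample_eval_subset(test, min(args.n_eval, len(test)), args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    for n_shot in (1, 5, 10, 20):
        spec = PromptSpec(DEFAULT_NER_DESCRIPTION, n_shot=n_shot, example_seed=args.seed)
        path = args.out / f"ner_{n_shot}shot.jsonl"
        with open(path, "w", encoding="utf-8") as fh:
            for sent in subset:
                fh.write(json.dumps({
                    "prompt": build_fewshot_prompt(spec, train, sent),
                    "gold": render_annotated(sent),
                }) + "\n")
        print(f"wrote {len(subset)} prompts ({n_shot}-shot) -> {path}")


if __name__ == "__main__":
    main()
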