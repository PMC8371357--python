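"""Letter-set construction, the delta-t dwell outcome, and bigram
similarity between consecutively submitted words."""

import numpy as np

from searchprime import (
    PrimingParams,
    bigram_similarity,
    bigrams,
    delta_t,
    generate_letterset,
    mean_letterset_time,
    session_bigram_similarity,
    simulate_anagram_session,
)

rng = np.random.default_rng(2)

print("three random letter-sets:", " ".join(generate_letterset(rng).letters for _ in range(3)))
print("bigrams of 'tale':", bigrams("tale"))
print("bigram similarity tale/gale:", bigram_similarity("tale", "gale"))

p = PrimingParams()  # practice_effect 0.7, no priming (delta = 0)
pre = simulate_anagram_session("pre", "clustered", p, rng)
post = simulate_anagram_session("post", "clustered", p, rng)
print(f"pre-test:  {len(pre.visits)} letter-sets, {pre.total_correct} correct words, "
      f"mean dwell {mean_letterset_time(pre):.1f} s")
print(f"post-test: {len(post.visits)} letter-sets, {post.total_correct} correct words, "
      f"mean dwell {mean_letterset_time(post):.1f} s")
print(f"delta-t = {delta_t(pre, post):.1f} s "
      "(negative: faster per letter-set after practice)")
print(f"consecutive-word bigram similarity (post): "
      f"{session_bigram_similarity(post):.2f}")

# delta-t is the study outcome: mean post-test dwell per letter-set minus
# mean pre-test dwell, excluding the set in which the 30th word was found.
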