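"""Score the three self-report instruments for a tiny survey.

Each trait is the mean of its 5-point Likert items (reverse-keyed items
flipped first), so all scores live on the same 1-5 scale; total
loneliness is the mean of its three sub-factors.
"""

import pandas as pd

from phototraits import score_survey

row = {"user_id": "demo"}
row |= {f"sd3_{i}": v for i, v in enumerate([4, 2, 5, 4, 3, 2, 4, 5, 4], 1)}
row |= {f"swls_{i}": v for i, v in enumerate([4, 4, 3, 5, 4], 1)}
row |= {f"selsa_f_{i}": v for i, v in enumerate([4, 2, 2, 4, 1], 1)}
row |= {f"selsa_s_{i}": v for i, v in enumerate([2, 4, 2, 3, 4], 1)}
row |= {f"selsa_r_{i}": v for i, v in enumerate([3, 3, 2, 2, 3], 1)}

traits = score_survey(pd.DataFrame([row]))
print(traits.round(2).to_string(index=False))
print("-> trait scores on the 1-5 scale; loneliness_total is the mean "
      "of the family/social/romantic sub-scores.")
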