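"""Independent reference implementations used as test oracles."""

from __future__ import annotations


def naive_tag(text, drug_surfaces, disease_surfaces, homonym_policy="drug"):
    """Oracle tagger: enumerate every substring, keep boundary-valid lexicon
    hits, then select longest-first / leftmost-first / DRUG-before-DISEASE."""
    low = text.lower()
    candidates = []
    for i in range(len(text)):
        for j in range(i + 1, len(text) + 1):
            before_ok = i == 0 or not low[i - 1].isalnum()
            after_ok = j == len(text) or not low[j].isalnum()
            if not (before_ok and after_ok):
                continue
            sub = low[i:j]
            if sub in drug_surfaces:
                candidates.append((i, j, "DRUG", drug_surfaces[sub]))
            if sub in disease_surfaces:
                candidates.append((i, j, "DISEASE", disease_surfaces[sub]))
    # same-span homonym policy
    spans = {}
    for c in candidates:
        spans.setdefault((c[0], c[1]), []).append(c)
    settled = []
    for span_cands in spans.values():
        types = {c[2] for c in span_cands}
        if len(types) > 1:
            if homonym_policy == "suppress":
                continue
            want = "DRUG" if homonym_policy == "drug" else "DISEASE"
            span_cands = [c for c in span_cands if c[2] == want]
        settled.extend(span_cands)
    settled.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2] != "DRUG", c[3]))
    accepted = []
    for c in settled:
        if all(c[1] <= a[0] or c[0] >= a[1] for a in accepted):
            accepted.append(c)
    return sorted(accepted)
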