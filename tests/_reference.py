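"""Naive reference implementation of the classification rules.

Deliberately independent of medtweet's matching machinery: no regexes, plain
character scans and token padding. Used as the oracle for equivalence tests
on small corpora.
"""

CREDENTIALS = (",M.D.", ",MD", ", MD", ",D.O.")


def _normalize(text: str) -> str:
    out = "".join(
        ch if (ch.isalnum() or ch == "_") else " " for ch in text.lower()
    )
    return " ".join(out.split())


def has_token_sequence(text: str, term: str) -> bool:
    return f" {_normalize(term)} " in f" {_normalize(text)} "


def hashtags(text: str) -> list[str]:
    tags = []
    i = 0
    while i < len(text):
        if text[i] == "#":
            j = i + 1
            while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                j += 1
            if j > i + 1:
                tags.append(text[i + 1 : j].lower())
            i = j
        else:
            i += 1
    return tags


def naive_classify(accounts, tweets, specialties) -> dict[str, str]:
    """Account -> final label, by direct rule-by-rule scanning."""
    geo = [t for t in tweets if t.language == "en" and t.country == "US"]
    by_id = {a.account_id: a for a in accounts}

    job_tweeters = set()
    for t in geo:
        for tag in hashtags(t.text):
            if tag in ("job", "jobs"):
                job_tweeters.add(t.account_id)
                break

    labels = {}
    for aid in {t.account_id for t in geo}:
        a = by_id[aid]
        included = (
            any(c in a.display_name for c in CREDENTIALS)
            or has_token_sequence(a.bio, "physician")
            or any(has_token_sequence(a.bio, s) for s in specialties)
        )
        handle_l, bio_l, name_l = a.handle.lower(), a.bio.lower(), a.display_name.lower()
        excluded = (
            "jobs" in handle_l
            or "jobs" in bio_l
            or "aspiring" in bio_l
            or "future" in bio_l
        )
        text_excluded = aid in job_tweeters and (
            "medical" in name_l or "surgery" in name_l
        )
        labels[aid] = (
            "physician"
            if included and not excluded and not text_excluded
            else "non_physician"
        )
    return labels
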