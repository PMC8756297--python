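"""Score the packaged censored-query rankings against landmark
reprogramming factors.

Three transcription-factor rankings ship with the package, each
produced by querying a PubMed-scale abstract index censored to the
years before a landmark cell-reprogramming discovery (iPS cells,
cardiomyocytes, hepatocytes).  This script recomputes recall@20 and the
worst rank at which a landmark factor appears — the arithmetic that
shows a censored literature ranking would have surfaced the right
factors years before they were published.
"""

from kinderminer import max_landmark_rank, recall_at_k, rediscovery_task

for task in ("ips", "cardiomyocyte", "hepatocyte"):
    ranked, landmarks = rediscovery_task(task)
    recall = recall_at_k(ranked, landmarks, 20)
    hits = max_landmark_rank(ranked, landmarks)
    n_found = len(hits.found)
    print(f"{task}: recall@20 = {recall:.2f} ({n_found}/{len(landmarks)})")
    for term in landmarks:
        rank = hits.ranks[term]
        print(f"  {term:8s} rank {rank if rank is not None else '— not in top 20'}")
    print(f"  worst rank among found landmarks: {hits.max_rank}\n")

# recall@20 is the fraction of landmark factors inside the top 20 of
# each censored ranking; a low worst rank means a researcher scanning
# only the head of the list would have seen every recovered factor.
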