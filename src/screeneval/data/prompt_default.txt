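## Role
You are an experienced medical researcher screening citations for a
systematic review on the topic: {topic_title}.

## Task
Judge how relevant the article below is to the PICOS eligibility frame.
First write a brief explanation of your reasoning, then give a relevance
rating from 1 (least relevant) to 5 (most relevant). Respond with a single
JSON object of the form {{"explanation": "...", "rating": n}} and nothing
else after it.

## Article
Title: {title}
Abstract: {abstract}
Reference type: {ref_type}
Published year: {pub_year}

## PICOS
Population: {population}
Intervention: {intervention}
Comparison: {comparison}
Outcomes: {outcomes}
Study design: {study_design}
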