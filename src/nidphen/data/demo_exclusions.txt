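# Manual-curation exclusion list: n-gram features judged irrelevant to
# neuroinfectious-disease classification, one space-joined term per line.
boston
heart rate
primary care
physical therapy
case manager
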