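# Two worked retrieval contexts for the cue-redintegration model.
# Upper block: an intact five-feature probe against its own trace and two
# permuted competitors.  Lower block: the same probe elaborated with three
# target-unique features (Q R N); the competitors are unchanged.
# '*' marks the target trace.

probe: C C 2 3 1
trace: C C 1 2 3
trace: * C C 2 3 1
trace: C C 3 1 2

probe: C C 2 3 1 Q R N
trace: C C 1 2 3
trace: * C C 2 3 1 Q R N
trace: C C 3 1 2
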