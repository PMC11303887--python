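member_code,canonical_code
272519000,2667000
410594000,2667000
260415000,2667000
260373001,52101004
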