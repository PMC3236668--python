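# Default noise patterns, one per line: "<group><TAB><python regex>".
# Groups and their semantics (applied by clinicolloc.preprocess):
#   quoted-reply       line rule:  drop any line whose start matches
#   attribution        line rule:  drop any line matching (reply attribution)
#   forwarded-block    block rule: drop from the first matching line to end
#   signature-delim    block rule: drop from the first matching line to end
#   signature-hint     heuristic:  a trailing block (after the last blank
#                      line, at most 6 lines) is dropped when any line
#                      matches one of these
#   virus-notice       line rule:  drop any line containing a match
#   client-notice      line rule:  drop any line containing a match
#   advertisement      line rule:  drop any line containing a match
#   embedded-image     span rule:  delete the matched placeholder text
quoted-reply	^\s*[>|]
attribution	^\s*On\b.{0,200}\bwrote:\s*$
forwarded-block	^\s*-{2,}\s*Original Message\s*-{2,}\s*$
forwarded-block	^\s*Begin forwarded message\b
forwarded-block	^\s*-{2,}\s*Forwarded message\s*-{2,}
signature-delim	^--\s*$
signature-hint	\b(?:DDS|DMD|D\.D\.S\.|D\.M\.D\.)\b
signature-hint	https?://|\bwww\.
signature-hint	\(\d{3}\)\s*\d{3}[-.]\d{4}|\b\d{3}[-.]\d{3}[-.]\d{4}\b
virus-notice	(?i)virus[- ]free|no virus found|checked by (?:avg|norton|mcafee)|scanned for viruses|spam[- ]free
client-notice	(?i)sent from my (?:iphone|ipad|blackberry|android)|microsoft outlook|outlook express
advertisement	(?i)\bunsubscribe\b|special offer|visit our website|sponsored by|click here
embedded-image	\[(?:image|cid|attachment)[^\]\n]*\]|<<[^>\n]*>>
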