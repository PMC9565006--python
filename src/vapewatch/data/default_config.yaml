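# Default study configuration.
#
# Keyword lists are editable plain text: token terms match whole tokens after
# punctuation is replaced by spaces, multi-word terms match as consecutive
# token phrases, and the symbols "$" / "%" match anywhere in the raw text.

ecig_keywords:
  - e-cig
  - e-cigs
  - ecig
  - ecigs
  - electroniccigarette
  - vape
  - vapers
  - vaping
  - vapes
  - e-liquid
  - ejuice
  - eliquid
  - e-juice
  - vapercon
  - vapeon
  - vapefam
  - vapenation
  - juul

promo_keywords:
  - dealer
  - deal
  - customer
  - promotion
  - promo
  - promos
  - discount
  - sale
  - free shipping
  - sell
  - "$"
  - "%"
  - dollar
  - offer
  - percent off
  - store
  - save
  - price
  - wholesale

# The first eleven entries are the documented core list; the remainder is a
# standard English function-word extension (articles, pronouns, auxiliaries,
# common prepositions/conjunctions) so that transaction mining is not swamped
# by grammatical glue.  Edit freely; mining output depends on this list.
stopwords:
  - i
  - is
  - are
  - do
  - we
  - it
  - in
  - "on"
  - at
  - to
  - the
  - a
  - an
  - and
  - or
  - but
  - of
  - for
  - with
  - my
  - your
  - his
  - her
  - their
  - our
  - this
  - that
  - these
  - those
  - was
  - were
  - be
  - been
  - being
  - am
  - you
  - he
  - she
  - they
  - me
  - him
  - them
  - us
  - so
  - not
  - "no"
  - just
  - have
  - has
  - had
  - will
  - would
  - can
  - could
  - from
  - by
  - as
  - if

# Cessation lexicon lemmas; surface variants are expanded by a fixed suffix
# table (see vapewatch.classify.expand_variants).
quit_lemmas:
  - quit
  - stop

min_support: 1000
min_rule_probability: 0.30
alpha: 0.05
age_split: 35

windows:
  pre_announcement: {start: 2019-06-13, end: 2019-07-31}
  between: {start: 2020-01-02, end: 2020-02-05}
  post_implementation: {start: 2020-02-06, end: 2020-10-12}
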