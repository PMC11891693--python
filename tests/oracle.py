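"""Brute-force interpreter-side language oracle.

Enumerates, by breadth-first search over ``step_all``, the set of
executable event sequences (those in which every event fires at least
one transition) up to a depth bound, each tagged with whether a marked
state is reachable after it.  Deliberately independent of the
flattening pipeline so the two can be compared."""

from guidechart.semantics import initial_configuration, is_marked, step_all


def interpreter_language(chart, depth):
    """dict: event-sequence tuple -> bool (marked reachable after it)."""

    def key(config, env):
        return (config.active, tuple(sorted(env.items())))

    cfg, env = initial_configuration(chart)
    by_key = {key(cfg, env): (cfg, env)}

    def marked(keys):
        return any(is_marked(chart, by_key[k][0])[0] for k in keys)

    start = frozenset({key(cfg, env)})
    lang = {(): marked(start)}
    frontier = {(): start}
    events = sorted(chart.events)
    for _ in range(depth):
        nxt = {}
        for seq, keys in frontier.items():
            for e in events:
                succ = set()
                for k in keys:
                    c, en = by_key[k]
                    for r in step_all(chart, c, e, dict(en)):
                        if r.ignored:
                            continue
                        kk = key(r.configuration, r.environment)
                        by_key[kk] = (r.configuration, r.environment)
                        succ.add(kk)
                if succ:
                    s2 = seq + (e,)
                    fs = frozenset(succ)
                    nxt[s2] = fs
                    lang[s2] = marked(fs)
        frontier = nxt
    return lang


def automaton_language(auto, depth):
    """Same language map computed by walking a flat automaton."""
    start = frozenset({auto.initial})

    def marked(qs):
        return any(q in auto.marked for q in qs)

    lang = {(): marked(start)}
    frontier = {(): start}
    events = sorted(auto.events)
    for _ in range(depth):
        nxt = {}
        for seq, qs in frontier.items():
            for e in events:
                succ = frozenset().union(*(auto.successors(q, e) for q in qs)) if qs else frozenset()
                if succ:
                    s2 = seq + (e,)
                    nxt[s2] = succ
                    lang[s2] = marked(succ)
        frontier = nxt
    return lang
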