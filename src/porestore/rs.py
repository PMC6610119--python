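"""Reed-Solomon coding over GF(2^8).

Systematic RS code with first consecutive root alpha^0 and generator
element alpha = 2 under the primitive polynomial x^8+x^4+x^3+x^2+1
(0x11d).  Supports errors-and-erasures decoding via Forney syndromes,
Berlekamp-Massey, Chien search and the Forney algorithm.  A codeword of
length n = k + nsym corrects e erasures and t errors whenever
e + 2t <= nsym.

Codewords are byte lists; position 0 is the first transmitted symbol
(coefficient of x^(n-1)).
"""

from __future__ import annotations

_PRIM = 0x11D

GF_EXP = [0] * 512
GF_LOG = [0] * 256
_x = 1
for _i in range(255):
    GF_EXP[_i] = _x
    GF_LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
for _i in range(255, 512):
    GF_EXP[_i] = GF_EXP[_i - 255]


class RSDecodeError(Exception):
    """Raised when a codeword is beyond the correction capability."""


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return GF_EXP[GF_LOG[a] + GF_LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("GF(256) division by zero")
    if a == 0:
        return 0
    return GF_EXP[(GF_LOG[a] - GF_LOG[b]) % 255]


def gf_pow(a: int, power: int) -> int:
    if a == 0:
        return 0
    return GF_EXP[(GF_LOG[a] * power) % 255]


def gf_inverse(a: int) -> int:
    return GF_EXP[255 - GF_LOG[a]]


def _poly_scale(p, x):
    return [gf_mul(c, x) for c in p]


def _poly_add(p, q):
    r = [0] * max(len(p), len(q))
    r[len(r) - len(p):] = [c for c in p]
    for i, c in enumerate(q):
        r[i + len(r) - len(q)] ^= c
    return r


def _poly_mul(p, q):
    r = [0] * (len(p) + len(q) - 1)
    for j, qj in enumerate(q):
        if qj == 0:
            continue
        for i, pi in enumerate(p):
            if pi:
                r[i + j] ^= gf_mul(pi, qj)
    return r


def _poly_eval(p, x):
    y = p[0]
    for c in p[1:]:
        y = gf_mul(y, x) ^ c
    return y


def generator_poly(nsym: int):
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, gf_pow(2, i)])
    return g


def rs_encode(msg, nsym: int):
    """Append nsym parity symbols to ``msg`` (systematic encoding)."""
    if len(msg) + nsym > 255:
        raise ValueError("codeword longer than 255 symbols")
    gen = generator_poly(nsym)
    rem = list(msg) + [0] * nsym
    for i in range(len(msg)):
        coef = rem[i]
        if coef != 0:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf_mul(gen[j], coef)
    return list(msg) + rem[len(msg):]


def _syndromes(msg, nsym):
    return [_poly_eval(msg, gf_pow(2, i)) for i in range(nsym)]


def _forney_syndromes(synd, erase_pos_rev, n_minus_1):
    # erase_pos_rev: positions counted from the codeword end
    fsynd = list(synd)
    for pos in erase_pos_rev:
        x = gf_pow(2, pos)
        for i in range(len(fsynd) - 1):
            fsynd[i] = gf_mul(fsynd[i], x) ^ fsynd[i + 1]
        fsynd.pop()
    return fsynd


def _berlekamp_massey(synd, n_checks):
    err_loc = [1]
    old_loc = [1]
    for i in range(n_checks):
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= gf_mul(err_loc[-(j + 1)], synd[i - j])
        old_loc = old_loc + [0]
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = _poly_scale(old_loc, delta)
                old_loc = _poly_scale(err_loc, gf_inverse(delta))
                err_loc = new_loc
            err_loc = _poly_add(err_loc, _poly_scale(old_loc, delta))
    while len(err_loc) and err_loc[0] == 0:
        err_loc.pop(0)
    return err_loc


def _find_error_positions(err_loc, nmess):
    errs = len(err_loc) - 1
    pos = []
    for i in range(nmess):  # positions counted from codeword end
        if _poly_eval(err_loc, gf_pow(2, i)) == 0:
            pos.append(nmess - 1 - i)
    if len(pos) != errs:
        raise RSDecodeError("error locator does not factor; too many errors")
    return pos


def _correct_errata(msg, synd, err_pos):
    # err_pos: 0-based positions (0 = first symbol); Forney algorithm.
    coef_pos = [len(msg) - 1 - p for p in err_pos]
    # errata locator: prod_i (1 + x * X_i), X_i = alpha^coef_pos[i]
    loc = [1]
    for p in coef_pos:
        loc = _poly_mul(loc, _poly_add([1], [gf_pow(2, p), 0]))
    # errata evaluator: x*S(x) * Lambda(x) mod x^(len(loc)), big-endian
    synd_be = list(reversed(synd)) + [0]
    eval_poly = _poly_mul(synd_be, loc)[-len(loc):]
    msg = list(msg)
    X = [gf_pow(2, p) for p in coef_pos]
    for i, xi in enumerate(X):
        xi_inv = gf_inverse(xi)
        # Lambda'(X_i^-1) in product form: prod_{j!=i} (1 + X_i^-1 X_j)
        loc_prime = 1
        for j, xj in enumerate(X):
            if j != i:
                loc_prime = gf_mul(loc_prime, 1 ^ gf_mul(xi_inv, xj))
        if loc_prime == 0:
            raise RSDecodeError("Forney derivative vanished")
        y = gf_mul(xi, _poly_eval(eval_poly, xi_inv))
        magnitude = gf_div(y, loc_prime)
        msg[err_pos[i]] ^= magnitude
    return msg


def rs_decode(received, nsym: int, erase_pos=None):
    """Correct ``received`` in place and return (message, codeword).

    erase_pos are 0-based positions of known erasures (symbols whose
    value is untrusted; any placeholder byte may be present there).
    Raises :class:`RSDecodeError` when e + 2t > nsym.
    """
    if len(received) > 255:
        raise ValueError("codeword longer than 255 symbols")
    erase_pos = list(erase_pos or [])
    if len(erase_pos) > nsym:
        raise RSDecodeError(
            f"{len(erase_pos)} erasures exceed parity budget {nsym}")
    msg = list(received)
    synd = _syndromes(msg, nsym)
    if max(synd) == 0:
        return msg[:-nsym], msg
    erase_rev = [len(msg) - 1 - p for p in erase_pos]
    fsynd = _forney_syndromes(synd, erase_rev, len(msg) - 1)
    err_loc = _berlekamp_massey(fsynd, len(fsynd))
    n_errors = len(err_loc) - 1
    if 2 * n_errors + len(erase_pos) > nsym:
        raise RSDecodeError("too many errors to correct")
    if n_errors:
        err_pos = _find_error_positions(list(reversed(err_loc)), len(msg))
    else:
        err_pos = []
    all_pos = sorted(set(err_pos) | set(erase_pos))
    msg = _correct_errata(msg, synd, all_pos)
    if max(_syndromes(msg, nsym)) != 0:
        raise RSDecodeError("decoding failed to produce a valid codeword")
    return msg[:-nsym], msg
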